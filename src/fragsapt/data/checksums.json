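{
 "calix6arene.sdf": "1f4d98dbc2c9129fdf65859f71c540ae3ef822e79863c0a380c773c53df24fbd",
 "conformer_relative_energies.csv": "5c2b766f24abb133da9a25f56ad5f3cc33b5f66c66c8c8d15d4aa174d5472627",
 "cx_gly_fragment_energies.csv": "8abb1d449df34f7a4b240da2ea7f4a1aa22a763c7ffff491664fa8ccf533b8a7",
 "cx_gly_fragment_reference.csv": "43801f17ad960b77a46fb5facbc154179d7a291599c878315d2a96b0854dbf5d",
 "cx_sapt0_components.csv": "b3b1b23e2e74cc6aa5fa625fa0d7ce97ee74f095ce514d1849f829d70c87c8f3",
 "pair_classification_reference.csv": "e8f560d3bf535ac97868808ed4e2528d9ef67ce4d516048bf79f4ec00e1eab9f",
 "tbc6arene.sdf": "a7b5fcb1b89c98f5806ceb17196edf1311340070324a25a66780fa1bb08b8062"
}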