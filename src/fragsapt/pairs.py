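"""Functional-group pair analysis of a partitioned interaction energy.

Given group-by-group effective SAPT components (electrostatics, first-order
exchange, effective induction, effective dispersion), each attractive pair
is classified by the magnitude ratios

    r_X = |E_X / E_int| ,   X in {elst, exch, ind_eff, disp_eff},

with a decision list calibrated against the archetypes of noncovalent
binding in calixarene–amino-acid complexes:

1. repulsive          E_int > 0
2. negligible         |E_int| below ~1 mH (partition noise)
3. typical H-bond     r_exch >= 1 and r_elst >= 1 and r_ind >= 0.5
                      (suffix "+disp" when additionally r_disp >= 0.3)
4. disp               r_disp >= 0.5 and r_exch >= 0.3
5. H⋯π                r_exch >= 0.3 (ring accepting a partially donated H)
6. elst               r_elst >= 0.3 and every other ratio < 0.3
7. unclassified       anything else

Rule 4 must precede rule 5: dispersion-dominated ring–ring pairs also carry
substantial exchange.  Strength bands follow the IUPAC hydrogen-bond
energy windows (strong >= 24 mH, medium 6.5–24 mH, weak < 6.5 mH; lower
edges inclusive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .energetics import EffectiveComponents

__all__ = [
    "GroupLabel",
    "PairMatrix",
    "BondClassification",
    "ClassifierThresholds",
    "ratios",
    "classify_pair",
    "strength_band",
    "find_paired_bindings",
    "interaction_graph_export",
    "read_pair_table",
]


@dataclass(frozen=True)
class GroupLabel:
    side: str  # "host" | "guest"
    name: str  # e.g. OH-3, Ph-5, COOH, NH2-1, Ring

    def __post_init__(self) -> None:
        if self.side not in ("host", "guest"):
            raise ValueError(f"group side must be host/guest, got {self.side!r}")


@dataclass
class ClassifierThresholds:
    """Ratio cutoffs of the decision list.  The defaults are calibrated on
    the printed archetype table and should normally be left alone."""

    first_order: float = 1.0   # r_elst and r_exch floor for a typical H-bond
    induction: float = 0.5     # r_ind floor for a typical H-bond
    significant: float = 0.3   # "component is significant" cutoff
    dispersion: float = 0.5    # r_disp floor for a dispersion-bound pair
    negligible_mh: float = 1.0


DEFAULT_THRESHOLDS = ClassifierThresholds()

STRENGTH_EDGES_MH = (6.5, 24.0, 64.0)  # weak|medium, medium|strong, strong cap


@dataclass
class BondClassification:
    label: str
    r_elst: float | None
    r_exch: float | None
    r_ind: float | None
    r_disp: float | None
    strength: str | None


def ratios(e: EffectiveComponents, e_total: float,
           negligible_mh: float = DEFAULT_THRESHOLDS.negligible_mh
           ) -> tuple[float, float, float, float]:
    """Unrounded magnitude ratios of the four effective components to the
    total.  Withheld (ValueError) when the total is in the partition-noise
    regime."""
    if abs(e_total) < negligible_mh:
        raise ValueError(
            f"total {e_total} mH below the negligible threshold; ratios withheld"
        )
    return (
        abs(e.elst / e_total),
        abs(e.exch / e_total),
        abs(e.ind_eff / e_total),
        abs(e.disp_eff / e_total),
    )


def classify_pair(
    e: EffectiveComponents,
    e_total: float | None = None,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
) -> BondClassification:
    t = thresholds
    total = e.total if e_total is None else e_total
    if total > 0:
        return BondClassification("repulsive", None, None, None, None, None)
    if abs(total) < t.negligible_mh:
        return BondClassification("negligible", None, None, None, None, None)
    r_elst, r_exch, r_ind, r_disp = ratios(e, total, t.negligible_mh)
    band = strength_band(total)
    if r_exch >= t.first_order and r_elst >= t.first_order and r_ind >= t.induction:
        label = "typical H-bond"
        if r_disp >= t.significant:
            label += "+disp"
    elif r_disp >= t.dispersion and r_exch >= t.significant:
        label = "disp"
    elif r_exch >= t.significant:
        label = "H⋯π"
    elif (
        r_elst >= t.significant
        and r_exch < t.significant
        and r_ind < t.significant
        and r_disp < t.significant
    ):
        label = "elst"
    else:
        label = "unclassified"
    return BondClassification(label, r_elst, r_exch, r_ind, r_disp, band)


def strength_band(e_total: float) -> str:
    """IUPAC-style strength band from the pair interaction energy (mH);
    lower band edges inclusive."""
    mag = abs(e_total)
    if mag >= STRENGTH_EDGES_MH[1]:
        return "strong"
    if mag >= STRENGTH_EDGES_MH[0]:
        return "medium"
    return "weak"


# ---------------------------------------------------------------------------
# pair matrix
# ---------------------------------------------------------------------------

class PairMatrix:
    """Group-by-group effective components for one complex."""

    def __init__(
        self,
        complex_id: str,
        conformer: str | None = None,
        host_type: str | None = None,
    ) -> None:
        self.complex_id = complex_id
        self.conformer = conformer
        self.host_type = host_type
        self.entries: dict[tuple[str, str], EffectiveComponents] = {}

    def add(self, host_group: str, guest_group: str, comp: EffectiveComponents) -> None:
        key = (host_group, guest_group)
        if key in self.entries:
            raise ValueError(f"duplicate pair {key} in {self.complex_id}")
        self.entries[key] = comp

    def totals(self) -> dict[tuple[str, str], float]:
        return {k: c.total for k, c in self.entries.items()}

    def complex_total(self) -> float:
        return sum(c.total for c in self.entries.values())

    def classify(self, thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS
                 ) -> dict[tuple[str, str], BondClassification]:
        return {k: classify_pair(c, thresholds=thresholds)
                for k, c in self.entries.items()}


def read_pair_table(path: str | Path) -> list[PairMatrix]:
    """Read the pair-table CSV dialect:
    complex_id, host_group, guest_group, elst, exch, ind_eff, disp_eff[, total]."""
    df = pd.read_csv(path)
    out: dict[str, PairMatrix] = {}
    for _, row in df.iterrows():
        cid = str(row["complex_id"])
        pm = out.setdefault(cid, PairMatrix(cid))
        pm.add(
            str(row["host_group"]),
            str(row["guest_group"]),
            EffectiveComponents(
                float(row["elst"]), float(row["exch"]),
                float(row["ind_eff"]), float(row["disp_eff"]),
            ),
        )
    return list(out.values())


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def find_paired_bindings(m: PairMatrix, similarity: float = 0.5) -> list[dict]:
    """Detect poly-dentate / poly-site binding motifs.

    Among the attractive pairs, collect those whose interaction energies are
    within ``similarity`` (fractional difference) of the strongest one.  Two
    or more such pairs form a motif: *poly-dentate* when one group binds
    several partners (A1-B1 and A1-B2), *poly-site* when distinct group
    pairs bind (A1-B1 and A2-B2).
    """
    if not m.entries:
        raise ValueError(f"pair matrix {m.complex_id} is empty")
    attract = [(k, t) for k, t in m.totals().items() if t < 0]
    if not attract:
        return []
    tmax = min(t for _, t in attract)  # most negative
    group = [(k, t) for k, t in attract if abs(t) >= (1.0 - similarity) * abs(tmax)]
    if len(group) < 2:
        return []
    motifs: list[dict] = []
    # shared-group (poly-dentate) motifs, on either side
    for side in (0, 1):
        by_group: dict[str, list[tuple[tuple[str, str], float]]] = {}
        for k, t in group:
            by_group.setdefault(k[side], []).append((k, t))
        for g, members in by_group.items():
            if len(members) >= 2:
                motifs.append(
                    {
                        "kind": "poly-dentate",
                        "shared_group": g,
                        "shared_side": "host" if side == 0 else "guest",
                        "pairs": [k for k, _ in members],
                        "energies": [t for _, t in members],
                    }
                )
    # disjoint pairs (poly-site)
    used_in_dentate = {k for mo in motifs for k in mo["pairs"]}
    disjoint: list[tuple[tuple[str, str], float]] = []
    for k, t in sorted(group, key=lambda kt: kt[1]):
        if all(k[0] != k2[0] and k[1] != k2[1] for k2, _ in disjoint):
            disjoint.append((k, t))
    if len(disjoint) >= 2 and not all(k in used_in_dentate for k, _ in disjoint):
        motifs.append(
            {
                "kind": "poly-site",
                "pairs": [k for k, _ in disjoint],
                "energies": [t for _, t in disjoint],
            }
        )
    return motifs


# ---------------------------------------------------------------------------
# graph export
# ---------------------------------------------------------------------------

_COMPONENT_GETTERS = {
    "total": lambda c: c.total,
    "elst": lambda c: c.elst,
    "exch": lambda c: c.exch,
    "ind_eff": lambda c: c.ind_eff,
    "disp_eff": lambda c: c.disp_eff,
}


def interaction_graph_export(m: PairMatrix, component: str = "total") -> list[dict]:
    """Bipartite edge list for the interaction graph: one edge per group
    pair with the signed component value; edge width proportional to its
    magnitude, sign denoting attraction (−) or repulsion (+)."""
    try:
        getter = _COMPONENT_GETTERS[component]
    except KeyError:
        raise ValueError(
            f"unknown component {component!r}; choose from {sorted(_COMPONENT_GETTERS)}"
        ) from None
    vals = {k: getter(c) for k, c in m.entries.items()}
    wmax = max((abs(v) for v in vals.values()), default=1.0) or 1.0
    return [
        {
            "host_group": k[0],
            "guest_group": k[1],
            "component": component,
            "value": v,
            "sign": "attractive" if v < 0 else "repulsive",
            "width": abs(v) / wmax,
        }
        for k, v in sorted(vals.items())
    ]


def write_edge_list(edges: list[dict], path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "tsv")
    if fmt == "json":
        path.write_text(json.dumps(edges, indent=1))
    else:
        df = pd.DataFrame(edges)
        df.to_csv(path, sep="\t", index=False)
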