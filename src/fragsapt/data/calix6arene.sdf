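calix6arene
     RDKit          3D

 84 90  0  0  0  0  0  0  0  0999 V2000
   -1.0164    5.3032   -2.0819 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1719    4.1453   -3.0434 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.1405    4.2282   -4.0583 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.2956    3.2002   -4.9874 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.4782    2.0747   -4.9225 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5025    1.9594   -3.9207 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3758    2.9909   -2.9768 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5634    2.8336   -1.9937 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.3748    0.7262   -3.8710 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.0645   -0.4166   -2.9738 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3424   -0.4802   -2.4001 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7268   -1.5790   -1.6295 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8418   -2.6346   -1.4183 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.4387   -2.6158   -1.9853 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.8059   -1.5006   -2.7518 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0581   -1.4769   -3.3067 O   0  0  0  0  0  0  0  0  0  0  0  0
    1.3714   -3.7874   -1.7653 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5116   -3.5292   -0.8025 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.7881   -3.2440   -1.3127 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.8584   -2.9934   -0.4590 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.6695   -3.0365    0.9200 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.4083   -3.3303    1.4674 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.3342   -3.5612    0.5899 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0818   -3.8532    1.0611 O   0  0  0  0  0  0  0  0  0  0  0  0
    3.2710   -3.3997    2.9720 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.7867   -2.1133    3.6072 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.7051   -1.0833    3.8566 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.2891    0.1117    4.4350 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.9489    0.2926    4.7716 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.9974   -0.7170    4.5400 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.4381   -1.9145    3.9502 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5776   -2.9419    3.6610 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4459   -0.4336    4.8958 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2139    0.3097    3.8251 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.8101   -0.4378    2.7965 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5173    0.1878    1.7728 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.6217    1.5754    1.7387 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.0079    2.3617    2.7235 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3321    1.7100    3.7742 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7955    2.5172    4.7427 O   0  0  0  0  0  0  0  0  0  0  0  0
   -2.1016    3.8771    2.7189 C   0  0  0  0  0  0  0  0  0  0  0  0
   -2.4578    4.5391    1.4024 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.7169    5.1524    1.2833 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.0904    5.7961    0.1060 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.2086    5.8420   -0.9702 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.9429    5.2403   -0.8874 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.5847    4.5812    0.3002 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3543    3.9750    0.3329 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1944    6.2423   -2.6252 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.0267    5.3973   -1.7543 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.7791    5.1051   -4.1355 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0488    3.2798   -5.7668 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.6050    1.2810   -5.6557 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.2570    3.3208   -1.2014 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.3848    1.0464   -3.5845 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.4720    0.3294   -4.8911 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.0607    0.3228   -2.5457 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.7226   -1.6138   -1.1977 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1540   -3.4790   -0.8078 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.5022   -0.7151   -2.8916 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.8056   -4.6621   -1.4167 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.7683   -4.1043   -2.7396 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.9487   -3.2128   -2.3887 H   0  0  0  0  0  0  0  0  0  0  0  0
    5.8395   -2.7704   -0.8693 H   0  0  0  0  0  0  0  0  0  0  0  0
    5.5202   -2.8481    1.5708 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.9900   -3.4692    1.9553 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.2409   -3.6639    3.4171 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.6289   -4.2457    3.2479 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.7529   -1.2056    3.5917 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.0074    0.9082    4.6127 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.6502    1.2452    5.2035 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.1571   -2.9254    4.2950 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4779    0.1093    5.8480 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.9782   -1.3611    5.1376 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7237   -1.5219    2.7752 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.9794   -0.4075    0.9902 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.1802    2.0287    0.9222 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7432    2.0284    5.5773 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1439    4.3101    3.0373 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.8327    4.1637    3.4865 H   0  0  0  0  0  0  0  0  0  0  0  0
   -4.4192    5.1327    2.1144 H   0  0  0  0  0  0  0  0  0  0  0  0
   -5.0679    6.2651    0.0286 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.5148    6.3518   -1.8809 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2877    3.4303    1.1389 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  7  1  0
  7  8  1  0
  6  9  1  0
  9 10  1  0
 10 11  1  0
 11 12  2  0
 12 13  1  0
 13 14  2  0
 14 15  1  0
 15 16  1  0
 14 17  1  0
 17 18  1  0
 18 19  1  0
 19 20  2  0
 20 21  1  0
 21 22  2  0
 22 23  1  0
 23 24  1  0
 22 25  1  0
 25 26  1  0
 26 27  1  0
 27 28  2  0
 28 29  1  0
 29 30  2  0
 30 31  1  0
 31 32  1  0
 30 33  1  0
 33 34  1  0
 34 35  1  0
 35 36  2  0
 36 37  1  0
 37 38  2  0
 38 39  1  0
 39 40  1  0
 38 41  1  0
 41 42  1  0
 42 43  1  0
 43 44  2  0
 44 45  1  0
 45 46  2  0
 46 47  1  0
 47 48  1  0
  7  2  2  0
 15 10  2  0
 23 18  2  0
 31 26  2  0
 39 34  2  0
 47 42  2  0
 46  1  1  0
  1 49  1  0
  1 50  1  0
  3 51  1  0
  4 52  1  0
  5 53  1  0
  8 54  1  0
  9 55  1  0
  9 56  1  0
 11 57  1  0
 12 58  1  0
 13 59  1  0
 16 60  1  0
 17 61  1  0
 17 62  1  0
 19 63  1  0
 20 64  1  0
 21 65  1  0
 24 66  1  0
 25 67  1  0
 25 68  1  0
 27 69  1  0
 28 70  1  0
 29 71  1  0
 32 72  1  0
 33 73  1  0
 33 74  1  0
 35 75  1  0
 36 76  1  0
 37 77  1  0
 40 78  1  0
 41 79  1  0
 41 80  1  0
 43 81  1  0
 44 82  1  0
 45 83  1  0
 48 84  1  0
M  END
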