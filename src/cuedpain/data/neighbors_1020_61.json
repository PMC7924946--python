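{
 "neighbors": {
  "AF3": [
   "AF7",
   "F1",
   "F3",
   "Fp1",
   "Fz"
  ],
  "AF4": [
   "AF8",
   "F2",
   "F4",
   "Fp2",
   "Fz"
  ],
  "AF7": [
   "AF3",
   "F3",
   "F5",
   "F7",
   "Fp1"
  ],
  "AF8": [
   "AF4",
   "F4",
   "F6",
   "F8",
   "Fp2"
  ],
  "C1": [
   "C3",
   "CP1",
   "CP3",
   "Cz",
   "FC1",
   "FC3"
  ],
  "C2": [
   "C4",
   "CP2",
   "CP4",
   "Cz",
   "FC2",
   "FC4"
  ],
  "C3": [
   "C1",
   "C5",
   "CP3",
   "CP5",
   "FC3",
   "FC5"
  ],
  "C4": [
   "C2",
   "C6",
   "CP4",
   "CP6",
   "FC4",
   "FC6"
  ],
  "C5": [
   "C3",
   "CP5",
   "FC5",
   "FT7",
   "T7",
   "TP7"
  ],
  "C6": [
   "C4",
   "CP6",
   "FC6",
   "FT8",
   "T8",
   "TP8"
  ],
  "CP1": [
   "C1",
   "CP3",
   "CPz",
   "Cz",
   "P1",
   "P3"
  ],
  "CP2": [
   "C2",
   "CP4",
   "CPz",
   "Cz",
   "P2",
   "P4"
  ],
  "CP3": [
   "C1",
   "C3",
   "CP1",
   "CP5",
   "P3",
   "P5"
  ],
  "CP4": [
   "C2",
   "C4",
   "CP2",
   "CP6",
   "P4",
   "P6"
  ],
  "CP5": [
   "C3",
   "C5",
   "CP3",
   "P5",
   "P7",
   "TP7"
  ],
  "CP6": [
   "C4",
   "C6",
   "CP4",
   "P6",
   "P8",
   "TP8"
  ],
  "CPz": [
   "CP1",
   "CP2",
   "Cz",
   "P1",
   "P2",
   "Pz"
  ],
  "Cz": [
   "C1",
   "C2",
   "CP1",
   "CP2",
   "CPz",
   "FC1",
   "FC2",
   "FCz"
  ],
  "F1": [
   "AF3",
   "F3",
   "FC1",
   "FCz",
   "Fz"
  ],
  "F2": [
   "AF4",
   "F4",
   "FC2",
   "FCz",
   "Fz"
  ],
  "F3": [
   "AF3",
   "AF7",
   "F1",
   "F5",
   "FC1",
   "FC3"
  ],
  "F4": [
   "AF4",
   "AF8",
   "F2",
   "F6",
   "FC2",
   "FC4"
  ],
  "F5": [
   "AF7",
   "F3",
   "F7",
   "FC3",
   "FC5"
  ],
  "F6": [
   "AF8",
   "F4",
   "F8",
   "FC4",
   "FC6"
  ],
  "F7": [
   "AF7",
   "F5",
   "FC5",
   "FT7"
  ],
  "F8": [
   "AF8",
   "F6",
   "FC6",
   "FT8"
  ],
  "FC1": [
   "C1",
   "Cz",
   "F1",
   "F3",
   "FC3",
   "FCz"
  ],
  "FC2": [
   "C2",
   "Cz",
   "F2",
   "F4",
   "FC4",
   "FCz"
  ],
  "FC3": [
   "C1",
   "C3",
   "F3",
   "F5",
   "FC1",
   "FC5"
  ],
  "FC4": [
   "C2",
   "C4",
   "F4",
   "F6",
   "FC2",
   "FC6"
  ],
  "FC5": [
   "C3",
   "C5",
   "F5",
   "F7",
   "FC3",
   "FT7"
  ],
  "FC6": [
   "C4",
   "C6",
   "F6",
   "F8",
   "FC4",
   "FT8"
  ],
  "FCz": [
   "Cz",
   "F1",
   "F2",
   "FC1",
   "FC2",
   "Fz"
  ],
  "FT7": [
   "C5",
   "F7",
   "FC5",
   "T7"
  ],
  "FT8": [
   "C6",
   "F8",
   "FC6",
   "T8"
  ],
  "Fp1": [
   "AF3",
   "AF7"
  ],
  "Fp2": [
   "AF4",
   "AF8"
  ],
  "Fz": [
   "AF3",
   "AF4",
   "F1",
   "F2",
   "FCz"
  ],
  "O1": [
   "O2",
   "Oz",
   "PO3",
   "PO7",
   "POz"
  ],
  "O2": [
   "O1",
   "Oz",
   "PO4",
   "PO8",
   "POz"
  ],
  "Oz": [
   "O1",
   "O2",
   "POz"
  ],
  "P1": [
   "CP1",
   "CPz",
   "P3",
   "PO3",
   "POz",
   "Pz"
  ],
  "P2": [
   "CP2",
   "CPz",
   "P4",
   "PO4",
   "POz",
   "Pz"
  ],
  "P3": [
   "CP1",
   "CP3",
   "P1",
   "P5",
   "PO3"
  ],
  "P4": [
   "CP2",
   "CP4",
   "P2",
   "P6",
   "PO4"
  ],
  "P5": [
   "CP3",
   "CP5",
   "P3",
   "P7",
   "PO3",
   "PO7"
  ],
  "P6": [
   "CP4",
   "CP6",
   "P4",
   "P8",
   "PO4",
   "PO8"
  ],
  "P7": [
   "CP5",
   "P5",
   "PO7",
   "TP7",
   "TP9"
  ],
  "P8": [
   "CP6",
   "P6",
   "PO8",
   "TP10",
   "TP8"
  ],
  "PO3": [
   "O1",
   "P1",
   "P3",
   "P5",
   "PO7",
   "POz"
  ],
  "PO4": [
   "O2",
   "P2",
   "P4",
   "P6",
   "PO8",
   "POz"
  ],
  "PO7": [
   "O1",
   "P5",
   "P7",
   "PO3"
  ],
  "PO8": [
   "O2",
   "P6",
   "P8",
   "PO4"
  ],
  "POz": [
   "O1",
   "O2",
   "Oz",
   "P1",
   "P2",
   "PO3",
   "PO4",
   "Pz"
  ],
  "Pz": [
   "CPz",
   "P1",
   "P2",
   "POz"
  ],
  "T7": [
   "C5",
   "FT7",
   "TP7",
   "TP9"
  ],
  "T8": [
   "C6",
   "FT8",
   "TP10",
   "TP8"
  ],
  "TP10": [
   "P8",
   "T8",
   "TP8"
  ],
  "TP7": [
   "C5",
   "CP5",
   "P7",
   "T7",
   "TP9"
  ],
  "TP8": [
   "C6",
   "CP6",
   "P8",
   "T8",
   "TP10"
  ],
  "TP9": [
   "P7",
   "T7",
   "TP7"
  ]
 },
 "positions": {
  "AF3": [
   -0.3383005751351914,
   0.7713203322696626
  ],
  "AF4": [
   0.35072183238145493,
   0.7633272029944227
  ],
  "AF7": [
   -0.672295072176298,
   0.840645593398351
  ],
  "AF8": [
   0.6725384893877407,
   0.8404037623819183
  ],
  "C1": [
   -0.24293218832698285,
   -0.0670781203340274
  ],
  "C2": [
   0.2555586441778472,
   -0.06528779856211561
  ],
  "C3": [
   -0.501981874856077,
   -0.08933709171110289
  ],
  "C4": [
   0.5146218558305536,
   -0.08357729629666279
  ],
  "C5": [
   -0.7699091566128727,
   -0.13195946470228798
  ],
  "C6": [
   0.7788911018609102,
   -0.11924077728124133
  ],
  "CP1": [
   -0.21970590959758954,
   -0.2925768211194813
  ],
  "CP2": [
   0.23740473347744154,
   -0.2911482646183273
  ],
  "CP3": [
   -0.44935920998025614,
   -0.3323646981745271
  ],
  "CP4": [
   0.4652409018123381,
   -0.3257310714618487
  ],
  "CP5": [
   -0.6852447658968128,
   -0.40077574842550884
  ],
  "CP6": [
   0.6985940904981414,
   -0.3865266442189434
  ],
  "CPz": [
   0.002305483120833401,
   -0.2827652937055329
  ],
  "Cz": [
   0.0025389214051968474,
   -0.05805510731214634
  ],
  "F1": [
   -0.22390486940954613,
   0.4636035507547265
  ],
  "F2": [
   0.24010548164749043,
   0.4686060250086597
  ],
  "F3": [
   -0.4582340644881512,
   0.4843853579116846
  ],
  "F4": [
   0.4715867349448195,
   0.4940451523034374
  ],
  "F5": [
   -0.695971934797027,
   0.5185884713996508
  ],
  "F6": [
   0.707752953495659,
   0.5192892995397521
  ],
  "F7": [
   -0.9310836233505935,
   0.562845045440483
  ],
  "F8": [
   0.9302568804986232,
   0.565742583056383
  ],
  "FC1": [
   -0.2488749171060205,
   0.19005135815490054
  ],
  "FC2": [
   0.2565681876455332,
   0.19500645663259483
  ],
  "FC3": [
   -0.5113448461508695,
   0.19301171604971565
  ],
  "FC4": [
   0.5207678586087073,
   0.19832167216276986
  ],
  "FC5": [
   -0.7872107543076378,
   0.1900696142296833
  ],
  "FC6": [
   0.7911218234979461,
   0.19829943806125933
  ],
  "FCz": [
   0.0026190284939842817,
   0.19073435376290815
  ],
  "FT7": [
   -1.0697015393364626,
   0.18699482074766527
  ],
  "FT8": [
   1.067323821060486,
   0.20111948958252446
  ],
  "Fp1": [
   -0.34753796716293006,
   0.9907489067799147
  ],
  "Fp2": [
   0.3485102858340119,
   0.9904525053355683
  ],
  "Fz": [
   0.0024520281794710376,
   0.4595550058847237
  ],
  "O1": [
   -0.24082965138800275,
   -0.9207046267663553
  ],
  "O2": [
   0.24474594174356867,
   -0.9198168337273455
  ],
  "Oz": [
   0.0008608797118267556,
   -0.9192211138588393
  ],
  "P1": [
   -0.18071425142715664,
   -0.5084501918130365
  ],
  "P2": [
   0.19849155622134573,
   -0.5005062621122089
  ],
  "P3": [
   -0.36902599568825545,
   -0.5485045709381
  ],
  "P4": [
   0.38266266254142195,
   -0.5400365982137725
  ],
  "P5": [
   -0.546809939292905,
   -0.6201142674713549
  ],
  "P6": [
   0.5524187165194026,
   -0.6176517393328054
  ],
  "P7": [
   -0.7129279062670362,
   -0.7229514141872113
  ],
  "P8": [
   0.7181086650140004,
   -0.7182325180354507
  ],
  "PO3": [
   -0.2681181296639513,
   -0.7406040556972762
  ],
  "PO4": [
   0.2713351438721424,
   -0.7439563547500945
  ],
  "PO7": [
   -0.48234743954471715,
   -0.857804334927776
  ],
  "PO8": [
   0.4876803968225475,
   -0.85526774597049
  ],
  "POz": [
   0.001492293829039736,
   -0.7072337609629634
  ],
  "Pz": [
   0.0019781277607115477,
   -0.49416640994800526
  ],
  "T7": [
   -1.0503199310067648,
   -0.19991135903425752
  ],
  "T8": [
   1.0533599632196111,
   -0.18596381349234686
  ],
  "TP10": [
   1.1219887555539267,
   -0.6124881062617729
  ],
  "TP7": [
   -0.9198181542410345,
   -0.4990156235519261
  ],
  "TP8": [
   0.9239651818533507,
   -0.49190954632987743
  ],
  "TP9": [
   -1.124058039098301,
   -0.6106717006377745
  ]
 }
}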