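study,block,dose_mg,metric,observed_nmol_L,published_predicted_nmol_L,published_ratio
Planchard,plasma,20,AUC,1964,2591,1.32
Planchard,plasma,20,Cmax,106.4,134.5,1.26
Planchard,plasma,20,Ctrough,51.2,87.2,1.70
Planchard,plasma,40,AUC,5640,5153,0.91
Planchard,plasma,40,Cmax,306.2,261.3,0.85
Planchard,plasma,40,Ctrough,179.3,168.0,0.94
Planchard,plasma,80,AUC,11930,12382,1.04
Planchard,plasma,80,Cmax,623.8,586.8,0.94
Planchard,plasma,80,Ctrough,386.4,406.7,1.05
Planchard,plasma,160,AUC,23910,26272,1.10
Planchard,plasma,160,Cmax,1255,1180.7,0.94
Planchard,plasma,160,Ctrough,784.4,805.5,1.03
Planchard,plasma,240,AUC,28310,38188,1.35
Planchard,plasma,240,Cmax,1491,1650.3,1.11
Planchard,plasma,240,Ctrough,929.1,1118.6,1.20
Zhao_40,plasma,40,AUC,5698,7105,1.25
Zhao_40,plasma,40,Cmax,303.4,309.1,1.02
Zhao_40,plasma,40,Ctrough,183.0,217.4,1.19
Zhao_80,plasma,80,AUC,9570,12306,1.29
Zhao_80,plasma,80,Cmax,550.4,598.5,1.09
Zhao_80,plasma,80,Ctrough,318,377.0,1.19
Harvey,plasma,80,AUC,11530,12923,1.12
Harvey,plasma,80,Cmax,620.1,572.0,0.92
Harvey,plasma,80,Ctrough,291.8,375.5,1.29
Grande,plasma,80,AUC,15780,13447,0.85
Grande,plasma,80,Cmax,291.8,535.7,1.84
Goldstein,intracranial,80,Ctrough,14.4,12.0,0.83
Yamaguchi,intracranial,80,Ctrough,4.1,10.3,2.51
Leeuw,intracranial,80,Ctrough,17.5,12.6,0.72
Fukuhara,intracranial,80,Ctrough,18.3,15.9,0.87
Ekman,intracranial,80,Ctrough,19.5,15.3,0.78
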