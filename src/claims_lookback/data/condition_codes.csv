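condition,pattern
Cerebrovascular disease,430-437.1
Cerebrovascular disease,437.3-438.xx
Congestive heart failure,428.xx
Congestive heart failure,398.91
Congestive heart failure,402.01
Congestive heart failure,402.11
Congestive heart failure,402.91
Congestive heart failure,404.01
Congestive heart failure,404.03
Congestive heart failure,404.11
Congestive heart failure,404.13
Congestive heart failure,404.91
Congestive heart failure,404.93
Chronic obstructive pulmonary disease,491.x-492.x
Chronic obstructive pulmonary disease,496
Depression,296.2x
Depression,296.3x
Depression,298.0
Depression,300.4
Depression,309.0
Depression,309.1
Depression,309.28
Depression,311
Diabetes,250.xx
Diabetes,357.2
Diabetes,362.0x
Diabetes,366.41
Diabetes,648.0x
Hip fracture,820.xx
Hypertension,401.xx-405.xx
Hypertension,437.2
Liver disease,571.2
Liver disease,571.4-571.49
Liver disease,571.5
Liver disease,571.6
Liver disease,571.8
Liver disease,571.9
Liver disease,572.2-572.8
Liver disease,456.0-456.21
Liver disease,V42.7
Myocardial infarction,410.xx
Myocardial infarction,411.0
Myocardial infarction,412.xx
Myocardial infarction,429.7x
Osteoarthritis,715.xx
Osteoporosis,733.xx
Renal disease,285.21
Renal disease,403.xx-404.xx
Renal disease,405.01
Renal disease,405.11
Renal disease,405.91
Renal disease,458.21
Renal disease,582.xx
Renal disease,583.xx
Renal disease,585
Renal disease,586
Renal disease,588.xx
Renal disease,593.71-593.73
Renal disease,V42.0
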