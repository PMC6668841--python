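component,variable,upper,points
respiration,pao2_fio2_ratio,100,4
respiration,pao2_fio2_ratio,200,3
respiration,pao2_fio2_ratio,300,2
respiration,pao2_fio2_ratio,400,1
respiration,pao2_fio2_ratio,inf,0
coagulation,platelets,20,4
coagulation,platelets,50,3
coagulation,platelets,100,2
coagulation,platelets,150,1
coagulation,platelets,inf,0
liver,bilirubin,1.2,0
liver,bilirubin,2.0,1
liver,bilirubin,6.0,2
liver,bilirubin,12.0,3
liver,bilirubin,inf,4
cardiovascular_map,mean_arterial_pressure,70,1
cardiovascular_map,mean_arterial_pressure,inf,0
cardiovascular_vasopressor,med_vasopressor,0.5,0
cardiovascular_vasopressor,med_vasopressor,inf,3
cns,gcs_total,6,4
cns,gcs_total,10,3
cns,gcs_total,13,2
cns,gcs_total,15,1
cns,gcs_total,inf,0
renal_creatinine,creatinine,1.2,0
renal_creatinine,creatinine,2.0,1
renal_creatinine,creatinine,3.5,2
renal_creatinine,creatinine,5.0,3
renal_creatinine,creatinine,inf,4
renal_urine,urine_output_24h,200,4
renal_urine,urine_output_24h,500,3
renal_urine,urine_output_24h,inf,0
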