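subject_id,event_type,time_years,dx_position
S0,NONCVD_DEATH,5.675624299086526,NA
S1,NONCVD_DEATH,8.91772697769518,NA
S2,NONCVD_DEATH,7.689210626047888,NA
S3,NONCVD_DEATH,6.524810986603339,NA
S4,NONCVD_DEATH,7.060554633918423,NA
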