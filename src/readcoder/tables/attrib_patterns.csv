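pattern_id,trigger,attribute,direction,scope_rule,modes
neg_no,no,negative,FORWARD,LIST,all
neg_not,not,negative,FORWARD,LIST,all
neg_did_not_show,did not show,negative,FORWARD,LIST,all
neg_no_evidence,no evidence of,negative,FORWARD,LIST,all
neg_without,without,negative,FORWARD,LIST,all
neg_never,never,negative,FORWARD,LIST,all
neg_nil,nil,negative,FORWARD,LIST,all
ph_ho,h/o,past_history,FORWARD,LIST,all
ph_history_of,history of,past_history,FORWARD,LIST,all
ph_previous,previous,past_history,FORWARD,LIST,all
ph_had_a,had a,past_history,FORWARD,LIST,all
ph_had_an,had an,past_history,FORWARD,LIST,all
ph_pmh,past medical history,past_history,FORWARD,LIST,all
fh_family_history,family history,family_history,FORWARD,LIST,all
fh_fh,fh,family_history,FORWARD,LIST,all
fh_mother,mother,family_history,FORWARD,LIST,all
fh_father,father,family_history,FORWARD,LIST,all
fh_brother,brother,family_history,FORWARD,LIST,all
fh_sister,sister,family_history,FORWARD,LIST,all
su_qmark,?,suspected,FORWARD,LIST,all
su_query,query,suspected,FORWARD,LIST,all
su_possible,possible,suspected,FORWARD,LIST,all
cod_phrase,cause of death,cause_of_death,FORWARD,SENTENCE,death
cod_cod,cod,cause_of_death,FORWARD,SENTENCE,death
tod_cd,cd,time_of_death,FORWARD,NEXT_VALUE,death
fu_recheck,recheck,follow_up,FORWARD,NEXT_VALUE,all
fu_review,review,follow_up,FORWARD,NEXT_VALUE,all
fu_rv,rv,follow_up,FORWARD,NEXT_VALUE,all
fu_fu,fu,follow_up,FORWARD,NEXT_VALUE,all
fu_fslash,f/u,follow_up,FORWARD,NEXT_VALUE,all
fu_rslash,r/v,follow_up,FORWARD,NEXT_VALUE,all
pulse_cue,pulse,pulse,FORWARD,NEXT_VALUE,all
pulse_hr,hr,pulse,FORWARD,NEXT_VALUE,all
pulse_bpm,bpm,pulse,BACKWARD,NEXT_VALUE,all
hb_cue,hb,haemoglobin,FORWARD,NEXT_VALUE,all
adm_date,admission date,admission_date,FORWARD,NEXT_VALUE,all
lmp_cue,lmp,lmp_date,FORWARD,NEXT_VALUE,all
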