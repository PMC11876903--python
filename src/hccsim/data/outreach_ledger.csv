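activity,hours,total_cost,one_time
Nurse Practitioner (screen patients for eligibility),289,22318.29,1
"Program Management (coordinate supplies, train staff)",50,2377.29,0
Computer/System support,40,1170.05,0
Language transcription/translation,10,282.13,1
Language validation,5,141.06,1
Prep recruit materials,20,545.22,0
Supplies for letters: Postage,,2369.40,0
"Supplies for letters: Materials (envelopes, labels, paper, printing)",,340.12,0
Patient outreach (staff time for calls and mailing),1040,40361.76,0
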