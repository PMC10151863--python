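# Placeholder medical stopword tier.
# Generic clinical-encounter vocabulary that carries little chapter-level
# signal in consultation speech. The tier mechanism (union with the english
# and custom tiers, removal before bigram formation) is the contract; edit
# this file to substitute a site-specific list.
patient
doctor
gp
nurse
clinic
surgery
appointment
prescription
prescribe
medication
medicine
tablet
tablets
dose
doses
symptom
symptoms
condition
diagnosis
treatment
treat
referral
refer
examination
examine
history
chronic
acute
mild
moderate
severe
hospital
ward
consultant
specialist
therapy
test
tests
result
results
scan
blood
sample
review
follow
followup
check
checkup
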