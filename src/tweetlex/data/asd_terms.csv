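term
autism
autistic
spectrum disorders
#asd
#actuallyautistic
#autismspeaks
#autismspeaks10
#autismparent
#autchat
#autismawareness
#liub
aspergers
aspies
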