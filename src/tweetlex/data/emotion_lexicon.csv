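category,form
fear,fear
fear,feared
fear,fearful
fear,fearing
fear,fears
fear,scare
fear,scared
anxiety,anxieties
anxiety,anxiety
anxiety,anxious
anxiety,anxiousness
paranoia,paranoia
paranoia,paranoiac
paranoia,paranoiacs
paranoia,paranoid
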