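category,form
obsess,obsessed
obsess,obsessing
obsess,obsession
obsess,obsessions
obsess,obsessive
obsess,obsessively
fixate,fixated
fixate,fixation
fixate,fixations
repeat,repeat
repeat,repeated
repeat,repeatedly
repeat,repeating
repeat,repeats
repeat,repetition
repeat,repetitions
routine,routinely
routine,routines
freak,freaked
freak,freaking
freak,freakout
freak,freakouts
clean,cleaned
clean,cleaning
check,checking
check,checked
check,checks
check,recheck
check,rechecks
check,rechecked
check,rechecking
count,counted
count,counting
count,counts
count,recount
count,recounted
count,recounting
count,recounts
hoard,hoarded
hoard,hoarder
hoard,hoarders
hoard,hoards
wash,washed
wash,washing
wash,washes
worry,worried
worry,worrying
excess,excessive
excess,excessively
excess,excessiveness
concern,concerned
concern,concerning
concern,concern
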