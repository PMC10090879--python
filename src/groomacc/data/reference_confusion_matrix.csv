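predicted,foraging,giving_grooming,receiving_grooming,resting,running,walking
foraging,6151,435,122,331,3,411
giving_grooming,500,5816,429,438,0,0
receiving_grooming,14,158,3599,182,0,0
resting,180,246,416,3243,0,9
running,4,0,0,0,122,18
walking,266,4,3,18,17,1701
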