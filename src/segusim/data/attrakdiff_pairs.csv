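group,index,negative,positive
PQ,0,complicated,simple
PQ,1,confusing,clearly structured
PQ,2,cumbersome,straightforward
PQ,3,impractical,practical
PQ,4,technical,human
PQ,5,unpredictable,predictable
PQ,6,unruly,manageable
ATT,0,bad,good
ATT,1,disagreeable,likeable
ATT,2,discouraging,motivating
ATT,3,rejecting,inviting
ATT,4,repelling,appealing
ATT,5,ugly,attractive
ATT,6,unpleasant,pleasant
HQ-I,0,alienating,integrating
HQ-I,1,cheap,premium
HQ-I,2,isolating,connective
HQ-I,3,separates me from people,brings me closer to people
HQ-I,4,tacky,stylish
HQ-I,5,unpresentable,presentable
HQ-I,6,unprofessional,professional
HQ-S,0,cautious,bold
HQ-S,1,conservative,innovative
HQ-S,2,conventional,inventive
HQ-S,3,dull,captivating
HQ-S,4,ordinary,novel
HQ-S,5,undemanding,challenging
HQ-S,6,unimaginative,creative
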