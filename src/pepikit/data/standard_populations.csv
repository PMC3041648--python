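# Standard populations for direct age standardization (weights per 100,000).
# world: Segi world standard population (Segi 1960, as used by IARC).
# european: European standard population (Waterhouse et al. 1976).
# african: African standard population (Doll, Payne & Waterhouse 1966).
standard,label,weight
world,0-4,12000
world,5-9,10000
world,10-14,9000
world,15-19,9000
world,20-24,8000
world,25-29,8000
world,30-34,6000
world,35-39,6000
world,40-44,6000
world,45-49,6000
world,50-54,5000
world,55-59,4000
world,60-64,4000
world,65-69,3000
world,70-74,2000
world,75-79,1000
world,80-84,500
world,85+,500
european,0-4,8000
european,5-9,7000
european,10-14,7000
european,15-19,7000
european,20-24,7000
european,25-29,7000
european,30-34,7000
european,35-39,7000
european,40-44,7000
european,45-49,7000
european,50-54,7000
european,55-59,6000
european,60-64,5000
european,65-69,4000
european,70-74,3000
european,75-79,2000
european,80-84,1000
european,85+,1000
african,0-4,10000
african,5-9,10000
african,10-14,10000
african,15-19,10000
african,20-24,10000
african,25-29,10000
african,30-34,10000
african,35-39,10000
african,40-44,5000
african,45-49,5000
african,50-54,3000
african,55-59,2000
african,60-64,2000
african,65-69,1000
african,70-74,1000
african,75-79,500
african,80-84,300
african,85+,200
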