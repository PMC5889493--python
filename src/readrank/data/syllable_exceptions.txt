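area 3
aria 3
business 2
cafe 2
camera 3
chaos 2
chocolate 2
colonel 2
coyote 3
create 2
dial 2
diet 2
doing 2
every 2
evening 2
family 3
favorite 3
fire 1
forte 2
going 2
heroes 2
hour 1
idea 3
interesting 4
ion 2
iron 2
karate 3
lion 2
naive 2
poem 2
poet 2
quiet 2
real 2
recipe 3
resume 3
science 2
seeing 2
several 3
theater 3
trial 2
violet 3
wednesday 2
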