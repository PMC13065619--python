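species,fa_label,mean_ug_per_mg
pika,12:0,6.4
pika,13:0,1.3
pika,14:0,46.6
pika,14:1,2.4
pika,15:0,11.5
pika,16:0,249.9
pika,16:1,55.1
pika,17:0,9.9
pika,17:1,3.3
pika,18:0,34.0
pika,18:1,104.8
pika,18:2,200.9
pika,18:3n3,266.6
pika,20:0,1.3
pika,20:1,1.2
pika,20:2,1.0
pika,20:3n6,0.0
pika,20:4n6,1.7
pika,20:3n3,0.0
pika,20:5,1.0
pika,21:0,0.0
pika,22:0,0.4
pika,22:1,0.0
pika,22:2,0.0
pika,22:6,0.6
pika,23:0,0.0
pika,24:0,0.0
pika,24:1,0.0
mouse,12:0,4.1
mouse,13:0,0.0
mouse,14:0,28.7
mouse,14:1,2.1
mouse,15:0,1.3
mouse,16:0,233.4
mouse,16:1,119.6
mouse,17:0,0.8
mouse,17:1,2.1
mouse,18:0,35.2
mouse,18:1,459.8
mouse,18:2,97.0
mouse,18:3n3,1.0
mouse,20:0,1.3
mouse,20:1,8.0
mouse,20:2,2.0
mouse,20:3n6,0.0
mouse,20:4n6,2.0
mouse,20:3n3,0.0
mouse,20:5,0.6
mouse,21:0,0.0
mouse,22:0,0.0
mouse,22:1,0.0
mouse,22:2,0.0
mouse,22:6,0.9
mouse,23:0,0.0
mouse,24:0,0.0
mouse,24:1,0.0
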