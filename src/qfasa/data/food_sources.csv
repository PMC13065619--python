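source,site,fa_label,mean_ug_per_mg,sd_ug_per_mg
grass,low,12:0,61.7,13.9
grass,low,13:0,0,0
grass,low,14:0,45.7,11.7
grass,low,14:1,0,0
grass,low,15:0,4.4,0.2
grass,low,16:0,285,37
grass,low,16:1,14.5,2.9
grass,low,17:0,6.1,0.5
grass,low,17:1,0,0
grass,low,18:0,73.5,9.2
grass,low,18:1,114.9,34.7
grass,low,18:2,149.7,34.5
grass,low,18:3n6,0,0
grass,low,18:3n3,98.3,19.9
grass,low,20:0,40.6,4.4
grass,low,20:1,0,0
grass,low,20:2,0,0
grass,low,20:3n6,0,0
grass,low,20:4n6,0,0
grass,low,20:3n3,0,0
grass,low,20:5,0,0
grass,low,21:0,5.5,0.4
grass,low,22:0,46.4,1.1
grass,low,22:1,5.6,0.5
grass,low,22:2,0,0
grass,low,22:6,0,0
grass,low,23:0,10.5,0.5
grass,low,24:0,37.4,1.9
grass,low,24:1,0,0
grass,medium,12:0,51,2.9
grass,medium,13:0,0,0
grass,medium,14:0,41.7,2.2
grass,medium,14:1,0,0
grass,medium,15:0,5.7,0.3
grass,medium,16:0,218.9,14.6
grass,medium,16:1,10.4,0.7
grass,medium,17:0,7.3,0.3
grass,medium,17:1,0,0
grass,medium,18:0,51.2,2
grass,medium,18:1,78.3,3.6
grass,medium,18:2,218.6,11.8
grass,medium,18:3n6,0,0
grass,medium,18:3n3,129.3,5.1
grass,medium,20:0,51.5,2.5
grass,medium,20:1,4.6,0.4
grass,medium,20:2,0,0
grass,medium,20:3n6,0,0
grass,medium,20:4n6,7.9,0.7
grass,medium,20:3n3,3.9,0.2
grass,medium,20:5,10.4,1.2
grass,medium,21:0,6.7,0.4
grass,medium,22:0,39.2,1.8
grass,medium,22:1,4.8,0.5
grass,medium,22:2,0,0
grass,medium,22:6,0,0
grass,medium,23:0,17.3,0.9
grass,medium,24:0,41.2,2
grass,medium,24:1,0,0
grass,high,12:0,28.6,0.6
grass,high,13:0,0,0
grass,high,14:0,24.9,0.5
grass,high,14:1,0,0
grass,high,15:0,5,0.1
grass,high,16:0,154.4,5.2
grass,high,16:1,19.3,0.7
grass,high,17:0,3.8,0.1
grass,high,17:1,0,0
grass,high,18:0,45.1,1.6
grass,high,18:1,106.6,5.7
grass,high,18:2,183.9,6.8
grass,high,18:3n6,5.3,0.3
grass,high,18:3n3,140.1,5.2
grass,high,20:0,65.8,1.7
grass,high,20:1,5,0.3
grass,high,20:2,3.5,0.1
grass,high,20:3n6,0,0
grass,high,20:4n6,27.8,1.7
grass,high,20:3n3,4,0.1
grass,high,20:5,33.3,1.8
grass,high,21:0,6.6,0.2
grass,high,22:0,64.1,1.6
grass,high,22:1,5.6,0.4
grass,high,22:2,0,0
grass,high,22:6,0,0
grass,high,23:0,13.1,0.3
grass,high,24:0,48.3,1.1
grass,high,24:1,5.8,0.3
roots,low,12:0,12.5,0.2
roots,low,13:0,0,0
roots,low,14:0,7.4,0.2
roots,low,14:1,0,0
roots,low,15:0,2.5,0.1
roots,low,16:0,104.4,6.4
roots,low,16:1,35.5,0.4
roots,low,17:0,1.9,0.1
roots,low,17:1,0,0
roots,low,18:0,19.5,2
roots,low,18:1,220.2,11.1
roots,low,18:2,357.7,16.9
roots,low,18:3n6,0,0
roots,low,18:3n3,82.2,4.6
roots,low,20:0,10.5,0.7
roots,low,20:1,17.8,1.1
roots,low,20:2,3.6,0.1
roots,low,20:3n6,0,0
roots,low,20:4n6,6.2,0.2
roots,low,20:3n3,0,0
roots,low,20:5,5,0.6
roots,low,21:0,2.1,0.1
roots,low,22:0,16.7,0.7
roots,low,22:1,40.5,1.4
roots,low,22:2,2.4,0
roots,low,22:6,0,0
roots,low,23:0,5.7,0.6
roots,low,24:0,32,0.5
roots,low,24:1,13.6,1
roots,medium,12:0,8.1,0.2
roots,medium,13:0,0,0
roots,medium,14:0,3.4,0.1
roots,medium,14:1,0,0
roots,medium,15:0,1.5,0.1
roots,medium,16:0,130.8,2.3
roots,medium,16:1,3.3,0.3
roots,medium,17:0,1.7,0
roots,medium,17:1,0,0
roots,medium,18:0,28.2,0.9
roots,medium,18:1,202.8,3.6
roots,medium,18:2,441.1,11.8
roots,medium,18:3n6,0,0
roots,medium,18:3n3,102.6,3.6
roots,medium,20:0,12.2,0.4
roots,medium,20:1,11.3,0.3
roots,medium,20:2,2.3,0.2
roots,medium,20:3n6,0,0
roots,medium,20:4n6,1.7,0.1
roots,medium,20:3n3,0,0
roots,medium,20:5,5.6,0.1
roots,medium,21:0,1.5,0.1
roots,medium,22:0,10.2,0.4
roots,medium,22:1,9.2,0.4
roots,medium,22:2,0,0
roots,medium,22:6,0,0
roots,medium,23:0,4.1,0.6
roots,medium,24:0,11.9,0.7
roots,medium,24:1,6.4,0.4
roots,high,12:0,9.4,0.3
roots,high,13:0,0,0
roots,high,14:0,3.3,0.8
roots,high,14:1,0,0
roots,high,15:0,1.8,0.1
roots,high,16:0,108.2,3.1
roots,high,16:1,4.2,2.5
roots,high,17:0,1.6,0.1
roots,high,17:1,0,0
roots,high,18:0,39.1,0.6
roots,high,18:1,159.5,7.1
roots,high,18:2,459.5,13
roots,high,18:3n6,0,0
roots,high,18:3n3,140.9,2.8
roots,high,20:0,12.8,0.2
roots,high,20:1,6.7,0.9
roots,high,20:2,2.2,0.2
roots,high,20:3n6,0,0
roots,high,20:4n6,2.2,0.3
roots,high,20:3n3,0,0
roots,high,20:5,2.2,0.2
roots,high,21:0,1.7,0.1
roots,high,22:0,11.6,0.4
roots,high,22:1,5.9,1.5
roots,high,22:2,0,0.1
roots,high,22:6,0,0
roots,high,23:0,5.5,0.2
roots,high,24:0,16.4,1.1
roots,high,24:1,5.5,0.8
feces,low,12:0,90.5,1.4
feces,low,13:0,12.4,0.3
feces,low,14:0,50.4,1.4
feces,low,14:1,0,0
feces,low,15:0,28.4,1
feces,low,16:0,258.7,7.4
feces,low,16:1,0,0
feces,low,17:0,31.7,1
feces,low,17:1,0,0
feces,low,18:0,157.4,7.1
feces,low,18:1,42.1,4.3
feces,low,18:2,31.2,1.6
feces,low,18:3n6,0,0
feces,low,18:3n3,29.9,1.9
feces,low,20:0,92.2,4
feces,low,20:1,0,0
feces,low,20:2,0,0
feces,low,20:3n6,0,0
feces,low,20:4n6,0,0
feces,low,20:3n3,0,0
feces,low,20:5,0,0
feces,low,21:0,0,0
feces,low,22:0,85.4,5.2
feces,low,22:1,0,0
feces,low,22:2,0,0
feces,low,22:6,0,0
feces,low,23:0,14.7,0.7
feces,low,24:0,75,6.6
feces,low,24:1,0,0
feces,medium,12:0,39.2,1.6
feces,medium,13:0,4.7,0.1
feces,medium,14:0,40.6,2.4
feces,medium,14:1,0,0
feces,medium,15:0,21.5,1.2
feces,medium,16:0,207.2,14.6
feces,medium,16:1,5.6,0.4
feces,medium,17:0,21.5,1.2
feces,medium,17:1,0,0
feces,medium,18:0,151,6.4
feces,medium,18:1,106.3,43.4
feces,medium,18:2,52.8,16.1
feces,medium,18:3n6,0,0
feces,medium,18:3n3,37.8,11.2
feces,medium,20:0,96.5,7.6
feces,medium,20:1,23.7,17.2
feces,medium,20:2,0,0
feces,medium,20:3n6,0,0
feces,medium,20:4n6,4.6,0.2
feces,medium,20:3n3,0,0
feces,medium,20:5,0,0
feces,medium,21:0,6.5,0.4
feces,medium,22:0,76,5.2
feces,medium,22:1,37.6,25.9
feces,medium,22:2,0,0
feces,medium,22:6,0,0
feces,medium,23:0,10.6,0.6
feces,medium,24:0,56.3,3.6
feces,medium,24:1,0,0
feces,high,12:0,44.3,2.5
feces,high,13:0,3.9,0.3
feces,high,14:0,40.9,2.1
feces,high,14:1,0,0
feces,high,15:0,14.7,0.6
feces,high,16:0,192.6,14.9
feces,high,16:1,8.9,0.4
feces,high,17:0,41.8,1.7
feces,high,17:1,0,0
feces,high,18:0,201.4,10.6
feces,high,18:1,90.3,17.8
feces,high,18:2,115.4,39
feces,high,18:3n6,0,0
feces,high,18:3n3,37.6,5.2
feces,high,20:0,63.1,4.8
feces,high,20:1,0,0
feces,high,20:2,0,0
feces,high,20:3n6,0,0
feces,high,20:4n6,0,0
feces,high,20:3n3,0,0
feces,high,20:5,0,0
feces,high,21:0,4.4,0.3
feces,high,22:0,67.4,4.6
feces,high,22:1,0,0
feces,high,22:2,0,0
feces,high,22:6,0,0
feces,high,23:0,9,0.8
feces,high,24:0,64.3,1.8
feces,high,24:1,0,0
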