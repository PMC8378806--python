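destination,2005,2006,2007,2008,2009,2010,2011,2012,2013,2014
Benin,10.6,16.9,62.4,122.0,73.2,74.9,70.9,33.7,34.4,35.5
Cote d'Ivoire,44.0,37.6,28.9,27.4,33.6,30.4,34.9,26.2,33.5,56.8
Ghana,90.6,125.7,111.5,93.3,85.2,140.0,152.3,136.0,82.0,82.7
Mali,0.8,2.5,2.0,2.8,1.9,1.0,2.1,2.1,1.3,1.1
Niger,5.6,13.9,12.0,17.7,19.9,14.3,11.7,15.3,15.6,33.8
Nigeria,34.9,60.3,118.6,132.3,101.1,83.4,84.4,138.2,140.4,121.0
Togo,17.1,8.2,21.4,13.3,12.6,12.9,15.5,12.7,9.8,13.5
Others,0.6,0.1,0.2,0.6,0.0,0.1,0.0,0.4,0.5,0.1
Total,204.2,265.2,357.0,409.3,327.6,357.1,371.9,364.6,317.4,344.4
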