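base,side,atom,x,y,z
A,1,C1',0.000000,5.108650,0.000000
A,1,N9,0.892661,3.928160,0.000000
A,1,C4,0.958917,2.549752,0.000000
A,1,C5,2.290335,2.186813,0.000000
A,1,N7,3.046942,3.340913,0.000000
A,1,C8,2.183132,4.417125,0.000000
A,1,C6,2.641730,0.852301,0.000000
A,1,N1,1.661707,-0.119272,0.000000
A,1,C2,0.330288,0.243667,0.000000
A,1,N3,-0.021107,1.578179,0.000000
A,1,N6,3.934557,0.499882,0.000000
A,1,H61,4.651821,1.210961,0.000000
A,1,H62,4.191737,-0.476826,0.000000
A,2,C1',0.000000,-5.108650,0.000000
A,2,N9,0.892661,-3.928160,0.000000
A,2,C4,0.958917,-2.549752,0.000000
A,2,C5,2.290335,-2.186813,0.000000
A,2,N7,3.046942,-3.340913,0.000000
A,2,C8,2.183132,-4.417125,0.000000
A,2,C6,2.641730,-0.852301,0.000000
A,2,N1,1.661707,0.119272,0.000000
A,2,C2,0.330288,-0.243667,0.000000
A,2,N3,-0.021107,-1.578179,0.000000
A,2,N6,3.934557,-0.499882,0.000000
A,2,H61,4.651821,-1.210961,0.000000
A,2,H62,4.191737,0.476826,0.000000
C,1,C1',0.000000,5.108650,0.000000
C,1,N1,1.473510,5.247102,0.000000
C,1,C2,1.111480,3.915436,0.000000
C,1,N3,2.083721,2.936076,0.000000
C,1,C4,3.417993,3.288382,0.000000
C,1,C5,3.780023,4.620047,0.000000
C,1,C6,2.807781,5.599408,0.000000
C,1,O2,-0.077763,3.601425,0.000000
C,1,N4,4.362053,2.337408,0.000000
C,1,H41,5.338585,2.595255,0.000000
C,1,H42,4.097089,1.362783,0.000000
C,2,C1',0.000000,-5.108650,0.000000
C,2,N1,1.473510,-5.247102,0.000000
C,2,C2,1.111480,-3.915436,0.000000
C,2,N3,2.083721,-2.936076,0.000000
C,2,C4,3.417993,-3.288382,0.000000
C,2,C5,3.780023,-4.620047,0.000000
C,2,C6,2.807781,-5.599408,0.000000
C,2,O2,-0.077763,-3.601425,0.000000
C,2,N4,4.362053,-2.337408,0.000000
C,2,H41,5.338585,-2.595255,0.000000
C,2,H42,4.097089,-1.362783,0.000000
G,1,C1',0.000000,5.108650,0.000000
G,1,N9,0.892661,3.928160,0.000000
G,1,C4,0.958917,2.549752,0.000000
G,1,C5,2.290335,2.186813,0.000000
G,1,N7,3.046942,3.340913,0.000000
G,1,C8,2.183132,4.417125,0.000000
G,1,C6,2.641730,0.852301,0.000000
G,1,N1,1.661707,-0.119272,0.000000
G,1,C2,0.330288,0.243667,0.000000
G,1,N3,-0.021107,1.578179,0.000000
G,1,O6,3.828429,0.528812,0.000000
G,1,N2,-0.621329,-0.699744,0.000000
G,1,H1,1.923980,-1.115320,0.000000
G,1,H21,-0.364149,-1.676452,0.000000
G,1,H22,-1.595773,-0.434115,0.000000
G,2,C1',0.000000,-5.108650,0.000000
G,2,N9,0.892661,-3.928160,0.000000
G,2,C4,0.958917,-2.549752,0.000000
G,2,C5,2.290335,-2.186813,0.000000
G,2,N7,3.046942,-3.340913,0.000000
G,2,C8,2.183132,-4.417125,0.000000
G,2,C6,2.641730,-0.852301,0.000000
G,2,N1,1.661707,0.119272,0.000000
G,2,C2,0.330288,-0.243667,0.000000
G,2,N3,-0.021107,-1.578179,0.000000
G,2,O6,3.828429,-0.528812,0.000000
G,2,N2,-0.621329,0.699744,0.000000
G,2,H1,1.923980,1.115320,0.000000
G,2,H21,-0.364149,1.676452,0.000000
G,2,H22,-1.595773,0.434115,0.000000
U,1,C1',0.000000,5.108650,0.000000
U,1,N1,1.473510,5.247102,0.000000
U,1,C2,1.111480,3.915436,0.000000
U,1,N3,2.083721,2.936076,0.000000
U,1,C4,3.417993,3.288382,0.000000
U,1,C5,3.780023,4.620047,0.000000
U,1,C6,2.807781,5.599408,0.000000
U,1,O2,-0.077763,3.601425,0.000000
U,1,O4,4.284555,2.415473,0.000000
U,1,H3,1.813510,1.942151,0.000000
U,2,C1',0.000000,-5.108650,0.000000
U,2,N1,1.473510,-5.247102,0.000000
U,2,C2,1.111480,-3.915436,0.000000
U,2,N3,2.083721,-2.936076,0.000000
U,2,C4,3.417993,-3.288382,0.000000
U,2,C5,3.780023,-4.620047,0.000000
U,2,C6,2.807781,-5.599408,0.000000
U,2,O2,-0.077763,-3.601425,0.000000
U,2,O4,4.284555,-2.415473,0.000000
U,2,H3,1.813510,-1.942151,0.000000
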