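name,lo,hi,units,constraint_class
cG_dark,2,4,uM,hard
Ca_dark,0.2,0.29,uM,hard
J_dark,25.75,27,pA,hard
PDE_sigma,0,750,um^-2,hard
alpha_max,50,500,uM s^-1,hard
alpha_ratio,2,20,,hard
m_cyc,2,2.5,,hard
K_cyc,130,140,nM,hard
JcG_max,1000,5000,pA,hard
m_cG,2,3.5,,hard
Jex_sat,1,10,pA,hard
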