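name,lo,hi,units,constraint_class
k_GE,0.05,1,um^2 s^-1,soft
nu_RG,30,330,s^-1,soft
k_R,1,200,s^-1,soft
k_E,5,150,s^-1,soft
D_R,1,2,um^2 s^-1,soft
D_G,1.2,3.2,um^2 s^-1,soft
D_E,0.8,1.6,um^2 s^-1,soft
D_cG,50,196,um^2 s^-1,soft
G_sigma,500,1500,um^-2,soft
PDE_sigma,10,100,um^-2,soft
beta_dark,1,1000,s^-1,soft
B_cG,1,2,,soft
kcat_Km,190,1810,uM^-1 s^-1,soft
alpha_max,50,500,uM s^-1,soft
alpha_ratio,2,20,,soft
m_cyc,2,2.5,,soft
K_cyc,130,140,nM,soft
B_Ca,10,30,,soft
JcG_max,1000,5000,pA,soft
m_cG,2.5,3.5,,soft
K_cG,10,30,uM,soft
f_Ca,0.2,0.35,,soft
Jex_sat,1,10,pA,soft
K_ex,0.02,5,uM,soft
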