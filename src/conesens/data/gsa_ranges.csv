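name,lo,hi,units,constraint_class
R_b,0.585,0.615,um,gsa
R_t,0.38,0.42,um,gsa
H,12.7,14.1,um,gsa
omega0,2.51,3.77,rad,gsa
eps0,16.4,17.2,nm,gsa
nu,0.61,0.71,,gsa
sigma,0.8,1.2,,gsa
k_GE,0.05,1,um^2 s^-1,gsa
nu_RG,30,330,s^-1,gsa
k_R,1,200,s^-1,gsa
k_E,5,150,s^-1,gsa
D_R,1,2,um^2 s^-1,gsa
D_G,1.1,3.2,um^2 s^-1,gsa
D_E,0.8,1.6,um^2 s^-1,gsa
D_cG,50,196,um^2 s^-1,gsa
D_Ca,12,18,um^2 s^-1,gsa
G_sigma,200,1500,um^-2,gsa
PDE_sigma,10,120,um^-2,gsa
beta_dark,1,1000,s^-1,gsa
B_cG,1,2,,gsa
kcat_Km,190,1810,uM^-1 s^-1,gsa
alpha_max,50,500,uM s^-1,gsa
a_min,0,1,,gsa
m_cyc,2,2.5,,gsa
K_cyc,130,140,nM,gsa
B_Ca,10,30,,gsa
JcG_max,1000,5000,pA,gsa
m_cG,2,3.5,,gsa
K_cG,10,30,uM,gsa
f_Ca,0.2,0.35,,gsa
Jex_sat,1,10,pA,gsa
K_ex,0.02,5,uM,gsa
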