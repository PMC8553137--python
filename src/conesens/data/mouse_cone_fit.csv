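name,lo,hi,units,constraint_class
alpha_max,55.8,,uM s^-1,fixed
alpha_ratio,5.51,,,fixed
beta_dark,8.57,,s^-1,fixed
B_cG,1.8,,,fixed
B_Ca,25.3,,,fixed
k_GE,0.33,,um^2 s^-1,fixed
R_b,0.6,,um,fixed
R_t,0.4,,um,fixed
omega0,3.141592653589793,,rad,fixed
D_cG,89.2,,um^2 s^-1,fixed
D_Ca,15,,um^2 s^-1,fixed
D_E,1.47,,um^2 s^-1,fixed
D_G,1.42,,um^2 s^-1,fixed
D_R,1.71,,um^2 s^-1,fixed
eps0,16.8,,nm,fixed
f_Ca,0.26,,,fixed
H,13.4,,um,fixed
JcG_max,3138,,pA,fixed
Jex_sat,8.79,,pA,fixed
kcat_Km,540,,uM^-1 s^-1,fixed
k_R,87.1,,s^-1,fixed
k_E,82.3,,s^-1,fixed
K_cyc,134,,nM,fixed
K_cG,14.2,,uM,fixed
K_ex,0.4,,uM,fixed
nu,0.65,,,fixed
nu_RG,212,,s^-1,fixed
n_discs,400,,,fixed
m_cyc,2.3,,,fixed
m_cG,2.9,,,fixed
G_sigma,253.82,,um^-2,fixed
PDE_sigma,115,,um^-2,fixed
sigma,1,,,fixed
R_sigma,10000,,um^-2,fixed
F,96500,,C mol^-1,fixed
N_Av,6.02e23,,mol^-1,fixed
cG_dark,2.65,,uM,derived
Ca_dark,0.204,,uM,derived
J_dark,26.1,,pA,derived
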