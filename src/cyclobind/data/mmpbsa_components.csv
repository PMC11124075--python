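host,mode,term,value,sd
alpha,BS,bonded,2.3,0.3
alpha,BP,bonded,2.8,0.3
beta,BS,bonded,2.0,0.3
beta,BP,bonded,1.9,0.4
gamma,BS,bonded,1.8,0.3
gamma,BP,bonded,1.3,0.4
alpha,BS,bonded_h,2.0,0.3
alpha,BP,bonded_h,2.6,0.3
beta,BS,bonded_h,1.8,0.3
beta,BP,bonded_h,1.7,0.3
gamma,BS,bonded_h,1.6,0.3
gamma,BP,bonded_h,1.1,0.3
alpha,BS,bonded_g,0.3,0.1
alpha,BP,bonded_g,0.3,0.1
beta,BS,bonded_g,0.2,0.1
beta,BP,bonded_g,0.2,0.1
gamma,BS,bonded_g,0.2,0.1
gamma,BP,bonded_g,0.2,0.1
alpha,BS,vdw,-19.1,0.1
alpha,BP,vdw,-19.6,0.1
beta,BS,vdw,-26.9,0.2
beta,BP,vdw,-24.4,0.1
gamma,BS,vdw,-23.3,0.9
gamma,BP,vdw,-22.2,0.4
alpha,BS,elec,-3.0,0.4
alpha,BP,elec,-6.8,0.2
beta,BS,elec,-5.2,0.3
beta,BP,elec,-9.0,0.5
gamma,BS,elec,-5.1,1.0
gamma,BP,elec,-4.2,0.5
alpha,BS,nonbonded,-22.1,0.3
alpha,BP,nonbonded,-26.4,0.4
beta,BS,nonbonded,-32.1,0.4
beta,BP,nonbonded,-33.4,0.5
gamma,BS,nonbonded,-28.3,1.6
gamma,BP,nonbonded,-26.4,0.3
alpha,BS,e_mm,-19.9,0.4
alpha,BP,e_mm,-23.5,0.4
beta,BS,e_mm,-30.1,0.4
beta,BP,e_mm,-31.5,0.6
gamma,BS,e_mm,-26.6,2.8
gamma,BP,e_mm,-25.1,0.4
alpha,BS,polar,12.4,0.3
alpha,BP,polar,15.4,0.2
beta,BS,polar,18.6,0.3
beta,BP,polar,20.4,0.4
gamma,BS,polar,17.1,1.2
gamma,BP,polar,14.9,0.2
alpha,BS,nonpolar,-1.7,0.0
alpha,BP,nonpolar,-1.8,0.0
beta,BS,nonpolar,-2.3,0.0
beta,BP,nonpolar,-2.2,0.0
gamma,BS,nonpolar,-2.3,0.1
gamma,BP,nonpolar,-2.3,0.0
alpha,BS,g_sol,10.7,0.3
alpha,BP,g_sol,13.6,0.2
beta,BS,g_sol,16.3,0.3
beta,BP,g_sol,18.1,0.4
gamma,BS,g_sol,14.8,1.1
gamma,BP,g_sol,12.7,0.2
alpha,BS,e_bind,-9.2,0.4
alpha,BP,e_bind,-10.0,0.3
beta,BS,e_bind,-13.8,0.3
beta,BP,e_bind,-13.4,0.4
gamma,BS,e_bind,-11.7,0.4
gamma,BP,e_bind,-12.5,0.4
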