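host,mode,phase,term,value
alpha,BS,gas,els,-17.3
alpha,BP,gas,els,-14.7
beta,BS,gas,els,-19.6
beta,BP,gas,els,-22.8
gamma,BS,gas,els,-12.9
gamma,BP,gas,els,-10.2
alpha,BS,water,els,-14.3
alpha,BP,water,els,-12.9
beta,BS,water,els,-17.3
beta,BP,water,els,-18.7
gamma,BS,water,els,-9.9
gamma,BP,water,els,-9.4
alpha,BS,gas,x,-7.9
alpha,BP,gas,x,-10.4
beta,BS,gas,x,-13.1
beta,BP,gas,x,-9.9
gamma,BS,gas,x,-5.3
gamma,BP,gas,x,-2.4
alpha,BS,water,x,-7.6
alpha,BP,water,x,-8.8
beta,BS,water,x,-11.4
beta,BP,water,x,-8.4
gamma,BS,water,x,-3.5
gamma,BP,water,x,-2.5
alpha,BS,gas,rep,40.1
alpha,BP,gas,rep,51.4
beta,BS,gas,rep,64.1
beta,BP,gas,rep,47.2
gamma,BS,gas,rep,33.0
gamma,BP,gas,rep,22.4
alpha,BS,water,rep,33.9
alpha,BP,water,rep,46.4
beta,BS,water,rep,58.7
beta,BP,water,rep,45.1
gamma,BS,water,rep,26.3
gamma,BP,water,rep,22.9
alpha,BS,gas,xrep,27.8
alpha,BP,gas,xrep,34.7
beta,BS,gas,xrep,43.2
beta,BP,gas,xrep,32.4
gamma,BS,gas,xrep,22.9
gamma,BP,gas,xrep,16.3
alpha,BS,water,xrep,23.2
alpha,BP,water,xrep,31.7
beta,BS,water,xrep,39.8
beta,BP,water,xrep,31.6
gamma,BS,water,xrep,18.8
gamma,BP,water,xrep,16.7
alpha,BS,gas,orb,-9.2
alpha,BP,gas,orb,-6.7
beta,BS,gas,orb,-8.7
beta,BP,gas,orb,-9.6
gamma,BS,gas,orb,-5.3
gamma,BP,gas,orb,-4.1
alpha,BS,water,orb,-7.5
alpha,BP,water,orb,-6.3
beta,BS,water,orb,-8.1
beta,BP,water,orb,-9.3
gamma,BS,water,orb,-4.5
gamma,BP,water,orb,-4.1
alpha,BS,gas,dftc,-11.1
alpha,BP,gas,dftc,-15.0
beta,BS,gas,dftc,-18.8
beta,BP,gas,dftc,-12.7
gamma,BS,gas,dftc,-11.4
gamma,BP,gas,dftc,-8.7
alpha,BS,water,dftc,-8.1
alpha,BP,water,dftc,-14.1
beta,BS,water,dftc,-17.8
beta,BP,water,dftc,-12.6
gamma,BS,water,dftc,-9.6
gamma,BP,water,dftc,-8.8
alpha,BS,gas,dc,-19.2
alpha,BP,gas,dc,-25.6
beta,BS,gas,dc,-32.5
beta,BP,gas,dc,-22.1
gamma,BS,gas,dc,-22.5
gamma,BP,gas,dc,-19.7
alpha,BS,water,dc,-13.7
alpha,BP,water,dc,-25.1
beta,BS,water,dc,-31.8
beta,BP,water,dc,-24.7
gamma,BS,water,dc,-21.3
gamma,BP,water,dc,-20.0
alpha,BS,gas,c,-30.3
alpha,BP,gas,c,-40.6
beta,BS,gas,c,-51.3
beta,BP,gas,c,-34.8
gamma,BS,gas,c,-33.8
gamma,BP,gas,c,-28.4
alpha,BS,water,c,-21.7
alpha,BP,water,c,-39.2
beta,BS,water,c,-49.6
beta,BP,water,c,-37.3
gamma,BS,water,c,-31.0
gamma,BP,water,c,-28.8
alpha,BS,gas,disp,-25.9
alpha,BP,gas,disp,-34.3
beta,BS,gas,disp,-43.4
beta,BP,gas,disp,-29.9
gamma,BS,gas,disp,-29.1
gamma,BP,gas,disp,-24.7
alpha,BS,water,disp,-18.7
alpha,BP,water,disp,-33.3
beta,BS,water,disp,-42.1
beta,BP,water,disp,-32.1
gamma,BS,water,disp,-26.9
gamma,BP,water,disp,-25.1
alpha,BS,gas,eint,-24.7
alpha,BP,gas,eint,-21.0
beta,BS,gas,eint,-28.5
beta,BP,gas,eint,-29.8
gamma,BS,gas,eint,-24.4
gamma,BP,gas,eint,-22.7
alpha,BS,water,eint,-17.3
alpha,BP,water,eint,-20.7
beta,BS,water,eint,-27.8
beta,BP,water,eint,-28.5
gamma,BS,water,eint,-22.5
gamma,BP,water,eint,-21.9
alpha,BS,gas,def_h,1.9
alpha,BP,gas,def_h,12.1
beta,BS,gas,def_h,3.8
beta,BP,gas,def_h,-0.3
gamma,BS,gas,def_h,3.8
gamma,BP,gas,def_h,0.5
alpha,BS,water,def_h,1.3
alpha,BP,water,def_h,14.0
beta,BS,water,def_h,3.7
beta,BP,water,def_h,5.5
gamma,BS,water,def_h,0.7
gamma,BP,water,def_h,0.0
alpha,BS,gas,def_g,0.2
alpha,BP,gas,def_g,0.2
beta,BS,gas,def_g,0.6
beta,BP,gas,def_g,0.6
gamma,BS,gas,def_g,0.2
gamma,BP,gas,def_g,0.1
alpha,BS,water,def_g,0.4
alpha,BP,water,def_g,0.2
beta,BS,water,def_g,0.7
beta,BP,water,def_g,0.4
gamma,BS,water,def_g,0.2
gamma,BP,water,def_g,0.1
alpha,BS,gas,def,2.1
alpha,BP,gas,def,12.3
beta,BS,gas,def,4.4
beta,BP,gas,def,0.3
gamma,BS,gas,def,3.9
gamma,BP,gas,def,0.6
alpha,BS,water,def,1.8
alpha,BP,water,def,14.2
beta,BS,water,def,4.4
beta,BP,water,def,5.9
gamma,BS,water,def,0.9
gamma,BP,water,def,0.1
alpha,BS,gas,polar,8.9
alpha,BP,gas,polar,5.8
beta,BS,gas,polar,8.7
beta,BP,gas,polar,12.3
gamma,BS,gas,polar,7.6
gamma,BP,gas,polar,7.2
alpha,BS,water,polar,9.1
alpha,BP,water,polar,5.0
beta,BS,water,polar,7.7
beta,BP,water,polar,16.7
gamma,BS,water,polar,6.1
gamma,BP,water,polar,6.0
alpha,BS,gas,nonpolar,-2.4
alpha,BP,gas,nonpolar,-2.4
beta,BS,gas,nonpolar,-3.5
beta,BP,gas,nonpolar,-2.6
gamma,BS,gas,nonpolar,-2.4
gamma,BP,gas,nonpolar,-1.9
alpha,BS,water,nonpolar,-2.6
alpha,BP,water,nonpolar,-2.3
beta,BS,water,nonpolar,-3.4
beta,BP,water,nonpolar,-3.9
gamma,BS,water,nonpolar,-2.1
gamma,BP,water,nonpolar,-1.8
alpha,BS,gas,sol,6.5
alpha,BP,gas,sol,3.4
beta,BS,gas,sol,5.2
beta,BP,gas,sol,9.7
gamma,BS,gas,sol,5.2
gamma,BP,gas,sol,5.3
alpha,BS,water,sol,6.5
alpha,BP,water,sol,2.7
beta,BS,water,sol,4.3
beta,BP,water,sol,12.8
gamma,BS,water,sol,4.0
gamma,BP,water,sol,4.2
alpha,BS,gas,gcorr,17.6
alpha,BP,gas,gcorr,15.0
beta,BS,gas,gcorr,19.2
beta,BP,gas,gcorr,20.8
gamma,BS,gas,gcorr,16.9
gamma,BP,gas,gcorr,16.7
alpha,BS,water,gcorr,16.9
alpha,BP,water,gcorr,14.3
beta,BS,water,gcorr,18.6
beta,BP,water,gcorr,19.8
gamma,BS,water,gcorr,16.8
gamma,BP,water,gcorr,16.4
alpha,BS,gas,gbind,1.5
alpha,BP,gas,gbind,9.7
beta,BS,gas,gbind,0.2
beta,BP,gas,gbind,1.0
gamma,BS,gas,gbind,1.6
gamma,BP,gas,gbind,0.0
alpha,BS,water,gbind,7.9
alpha,BP,water,gbind,10.5
beta,BS,water,gbind,-0.6
beta,BP,water,gbind,10.0
gamma,BS,water,gbind,-0.9
gamma,BP,water,gbind,-1.1
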