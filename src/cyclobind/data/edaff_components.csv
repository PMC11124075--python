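host,charge_method,phase,mode,elec,rep,disp,ff
alpha,MK,gas,BS,-9.4,8.4,-23.1,-24.1
alpha,MK,gas,BP,-3.4,16.3,-32.7,-19.8
alpha,MK,water,BS,-8.3,6.6,-20.0,-21.7
alpha,MK,water,BP,-3.0,14.4,-31.6,-20.2
alpha,CHELPG,gas,BS,-9.4,8.4,-23.1,-24.1
alpha,CHELPG,gas,BP,-3.0,16.3,-32.7,-19.3
alpha,CHELPG,water,BS,-8.4,6.6,-20.0,-21.8
alpha,CHELPG,water,BP,-2.5,14.4,-31.6,-19.8
alpha,RESP,gas,BS,-9.6,8.4,-23.1,-24.2
alpha,RESP,gas,BP,-3.7,16.3,-32.7,-20.1
alpha,RESP,water,BS,-8.5,6.6,-20.0,-21.9
alpha,RESP,water,BP,-3.0,14.4,-31.6,-20.2
alpha,RESP2,gas,BS,-10.8,8.4,-23.1,-25.5
alpha,RESP2,gas,BP,-4.4,16.3,-32.7,-20.8
alpha,RESP2,water,BS,-9.5,6.6,-20.0,-22.9
alpha,RESP2,water,BP,-3.6,14.4,-31.6,-20.8
alpha,FFMD,gas,BS,-9.9,8.4,-23.1,-24.5
alpha,FFMD,gas,BP,-2.8,16.3,-32.7,-19.2
alpha,FFMD,water,BS,-8.4,6.6,-20.0,-21.8
alpha,FFMD,water,BP,-1.8,14.4,-31.6,-19.1
beta,MK,gas,BS,-4.2,19.8,-41.7,-26.0
beta,MK,gas,BP,-10.7,10.6,-27.1,-27.3
beta,MK,water,BS,-3.3,17.8,-40.0,-25.5
beta,MK,water,BP,-10.6,9.8,-26.4,-27.1
beta,CHELPG,gas,BS,-3.6,19.8,-41.7,-25.5
beta,CHELPG,gas,BP,-10.5,10.6,-27.1,-27.0
beta,CHELPG,water,BS,-2.8,17.8,-40.0,-25.1
beta,CHELPG,water,BP,-10.4,9.8,-26.4,-26.9
beta,RESP,gas,BS,-4.7,19.8,-41.7,-26.5
beta,RESP,gas,BP,-10.4,10.6,-27.1,-26.9
beta,RESP,water,BS,-4.0,17.8,-40.0,-26.2
beta,RESP,water,BP,-10.2,9.8,-26.4,-26.8
beta,RESP2,gas,BS,-6.0,19.8,-41.7,-27.8
beta,RESP2,gas,BP,-12.9,10.6,-27.1,-29.4
beta,RESP2,water,BS,-5.1,17.8,-40.0,-27.4
beta,RESP2,water,BP,-12.6,9.8,-26.4,-29.2
beta,FFMD,gas,BS,-3.9,19.8,-41.7,-25.7
beta,FFMD,gas,BP,-11.4,10.6,-27.1,-27.9
beta,FFMD,water,BS,-2.9,17.8,-40.0,-25.2
beta,FFMD,water,BP,-11.3,9.8,-26.4,-27.9
gamma,MK,gas,BS,-4.5,9.1,-27.8,-23.2
gamma,MK,gas,BP,-4.3,6.3,-23.8,-21.8
gamma,MK,water,BS,-3.2,9.8,-26.4,-21.6
gamma,MK,water,BP,-3.5,7.1,-25.4,-20.9
gamma,CHELPG,gas,BS,-4.1,9.1,-27.8,-22.8
gamma,CHELPG,gas,BP,-4.1,6.3,-23.8,-21.6
gamma,CHELPG,water,BS,-3.0,9.8,-26.4,-21.4
gamma,CHELPG,water,BP,-3.4,7.1,-25.4,-20.7
gamma,RESP,gas,BS,-4.0,9.1,-27.8,-22.7
gamma,RESP,gas,BP,-4.2,6.3,-23.8,-21.7
gamma,RESP,water,BS,-3.3,9.8,-26.4,-21.7
gamma,RESP,water,BP,-3.3,7.1,-25.4,-20.7
gamma,RESP2,gas,BS,-5.5,9.1,-27.8,-24.2
gamma,RESP2,gas,BP,-5.5,6.3,-23.8,-22.9
gamma,RESP2,water,BS,-4.6,9.8,-26.4,-23.0
gamma,RESP2,water,BP,-4.5,7.1,-25.4,-21.8
gamma,FFMD,gas,BS,-6.2,9.1,-27.8,-24.9
gamma,FFMD,gas,BP,-5.3,6.3,-23.8,-22.7
gamma,FFMD,water,BS,-3.8,9.8,-26.4,-22.2
gamma,FFMD,water,BP,-4.3,7.1,-25.4,-21.7
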