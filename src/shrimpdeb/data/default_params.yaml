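# Estimated DEB parameters for kuruma shrimp (Penaeus japonicus)
# at a reference temperature of 20 degC.
z: 0.76          # zoom factor, female (-)
zm: 0.71         # zoom factor, male (-)
Fm_max: 6.5      # maximum specific searching rate (J cm-2 d-1)
v_dot: 0.0336    # energy conductance (cm d-1), stored for reference
EG: 4439         # volume-specific cost for structure (J cm-3)
EM: 13235        # maximum reserve density (J cm-3)
kappa: 0.98      # somatic allocation fraction (-)
kappaR: 0.95     # reproduction efficiency (-)
deltaM: 0.1585   # shape coefficient (-)
pAm: 1823        # max surface-specific assimilation rate (J cm-2 d-1)
pM: 569          # volume-specific maintenance rate (J cm-3 d-1)
T1: 293          # reference temperature (K)
TA: 6200         # Arrhenius temperature (K)
TH: 302          # upper tolerance boundary (K)
TL: 283          # lower tolerance boundary (K)
TAH: 33800       # Arrhenius temperature at upper boundary (K)
TAL: 13300       # Arrhenius temperature at lower boundary (K)
rho: 1           # volume-specific weight density (g cm-3)
EHb: 0.0013      # maturity at birth (J)
EHj: 0.0966      # maturity at metamorphosis (J)
EHp: 2349        # maturity at puberty (J)
ha: 1.8e-7       # Weibull aging acceleration (d-2)
sG: 0.0001       # Gompertz stress coefficient (-)
# muE (reserve energy content, J g-1) is calibrated at load time from the
# ultimate-state identity unless given here explicitly.
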