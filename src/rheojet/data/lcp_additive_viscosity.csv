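name,additive,mw,conc_aqueous,conc_unit,conc_total,conc_display,eta_lve_mean,eta_lve_sd,eta_jet_mean,eta_jet_sd,stability
LCP no additive,,,,none,,N/A,5.7e6,0.9e6,3.6e4,0.09e4,+
LCP 20% PEG 300,PEG 300,300,20,pct_vv,6,6%,1.8e5,0.7e5,2.9e3,0.04e3,+
LCP 50% PEG 300,PEG 300,300,50,pct_vv,15,15%,3.7e4,0.4e4,1.3e3,0.2e3,-
LCP 10% PEG 1500,PEG 1500,1500,10,pct_vv,3,3%,2.7e4,0.6e4,1.6e3,0.2e3,-
LCP 20% PEG 1500,PEG 1500,1500,20,pct_vv,6,6%,3.4e3,0.2e3,5.2e2,0.03e2,-
LCP 2.5% PEG 6000,PEG 6000,6000,2.5,pct_vv,0.75,0.75%,3.1e4,0.7e4,1.5e3,0.1e3,-
LCP 10% PEG 6000,PEG 6000,6000,10,pct_vv,3,3%,1.4e3,0.1e3,2.3e2,0.2e2,--
LCP 5% MPD,MPD,118.17,5,pct_vv,1.5,1.5%,9.8e5,1.1e5,6.8e3,0.7e3,+
LCP 7.5% MPD,MPD,118.17,7.5,pct_vv,2.25,2.25%,5.4e5,0.7e5,2.5e3,0.3e3,+
LCP 10% MPD,MPD,118.17,10,pct_vv,3,3%,2.4e4,0.4e4,1.1e3,0.2e3,-
LCP 12.5% MPD,MPD,118.17,12.5,pct_vv,3.75,3.75%,7.5e3,1.2e3,2.8e2,0.2e2,-
LCP 15% MPD,MPD,118.17,15,pct_vv,4.5,4.5%,1.3e3,0.7e3,7.5e1,1.2e1,--
LCP 100 mM CaCl2,CaCl2,,100,mM,30,30 mM,3.2e6,0.5e6,2.4e4,0.5e4,+
LCP 1 M (NH4)2SO4,(NH4)2SO4,,1000,mM,300,300 mM,3.8e5,0.9e5,2.1e3,0.4e3,-
LCP 1 M NaCl,NaCl,,1000,mM,300,300 mM,1.9e6,0.4e6,3.6e4,0.04e4,+
LCP 500 mM LiCl,LiCl,,500,mM,150,150 mM,2.9e6,0.4e6,1.1e4,0.02e4,+
LCP 500 mM sodium malonate,sodium malonate,,500,mM,150,150 mM,3.8e6,0.6e6,1.8e4,0.02e4,+
LCP 60/40 (v/v) 6% DDM,DDM,,6,pct_vv,2.4,2.4%,1.9e6,0.4e6,4.1e3,0.4e3,+
LCP 50/50 (v/v) 10% DDM,DDM,,10,pct_vv,5,5%,1.4e6,0.2e6,3.6e3,0.4e3,+
LCP 40/60 (v/v) 14% DDM,DDM,,14,pct_vv,8.4,8.4%,3.9e5,0.8e5,2.5e3,0.2e3,-
LCP 85/15 (v/v) 10% PEG 6000,PEG 6000,6000,10,pct_vv,1.5,1.5%,1.3e4,0.09e4,9.5e2,0.2e2,-
LCP 10% PEG 6000 + 50% Pluronic F-127,PEG 6000 + Pluronic F-127,,10,pct_vv,,1.5%/17.5%,7.9e5,0.6e5,2.8e3,0.4e3,+
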