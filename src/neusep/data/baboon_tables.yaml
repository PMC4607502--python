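# Published rate constants and initial conditions for the baboon E. coli
# bacteremia calibration.  Each parameter entry is [mean, posterior SD];
# SD = 0 marks a constant fixed to literature values.
#
# Units: time in hours; pathogen in CFU; neutrophils in 1e3 cells/ul;
# IL-8 and fMLP in nM; creatinine in nM; elastase/alpha1-PI in ng/ml;
# receptor fractions and damage dimensionless.
shared:
  k_PG:        [1.0, 0.0]            # pathogen growth, 1/h
  k_P_NKM:     [145.5391, 0.040553]  # neutrophil-induced pathogen death
  k_PL:        [1.6533e-7, 2.3409e-7]  # pathogen population limit
  k_p:         [271.9904, 352.4858]  # saturable pathogen decay, CFU/h
  k_pd:        [1000.0, 0.0]         # pathogen decay half-saturation, CFU
  k_NB:        [0.1, 0.0]            # basal neutrophil natural decay, 1/h
  k_NK:        [0.0330, 0.0275]      # killer neutrophil decay, 1/h
  k_NM:        [0.1244, 0.1936]      # migratory neutrophil decay, 1/h
  k_NKM:       [0.1176, 0.1772]      # dual-phenotype decay, 1/h
  k_NM_NK_IL8: [168.7708, 260.7247]  # CXCR-1-driven N_M -> N_KM transition
  k_IL8_P:     [2.7810e-6, 2.0441e-6]  # pathogen-induced IL-8 production
  k_IL8_D:     [5.7938e-9, 7.9615e-9]  # damage-induced IL-8 production
  k_IL8:       [0.3352, 0.0261]      # IL-8 decay, 1/h
  k_D_NK:      [0.0319, 0.0285]      # killer-neutrophil damage rate
  k_Drec:      [7.0147, 8.8870]      # damage recovery rate, 1/h
  k_filter_on: [6.1698e-4, 8.2047e-4]  # filter production, 1/(CFU h)
  k_r1:        [79.2, 0.0]           # CXCR-1 dissociation, 1/h
  k_r2:        [79.2, 0.0]           # CXCR-2 dissociation, 1/h
  K_D_IL8:     [2.5e-3, 0.0]         # IL-8/receptor affinity constant
  k_i1:        [5.196, 0.0]          # CXCR-1 complex internalization, 1/h
  k_i1p:       [0.612, 0.0]          # CXCR-1 recycle, 1/h
  k_i2:        [20.796, 0.0]         # CXCR-2 complex internalization, 1/h
  k_i2p:       [0.144, 0.0]          # CXCR-2 recycle, 1/h
  k_fMLP:      [5.9866e-7, 1.3864e-6]  # pathogen-induced fMLP production
  k_fMLPd:     [622.9280, 1.6952e3]  # fMLP production half-saturation, CFU
  k_fMLP_D:    [9.8425e4, 1.7303e5]  # fMLP decay, 1/h
  k_fMLP_NB:   [0.0021, 0.0025]      # fMLP-pathway N_B -> N_KM exit, 1/h
  k_NE:        [0.0351, 0.0209]      # N_K -> elastase/alpha1-PI scaling
group:
  survivor:
    k_NG:         [0.506, 0.0]       # baseline neutrophil source
    k_creat:      [0.1591, 0.0]      # creatinine clearance, 1/h
    k_NB_G:       [6.6447e5, 1.5092e6]
    k_NB_Gd:      [8.8322e4, 1.7149e5]
    k_NK_IL8:     [8.9617e3, 4.9596e3]
    k_NM_IL8:     [4.8740e3, 6.5289e3]
    k_NK_NM_IL8:  [3.9436, 12.6137]
    k_IL8_Pd:     [1.2814e4, 1.2646e4]
    k_filter_off: [0.0813, 0.0145]
  nonsurvivor:
    k_NG:         [0.54417, 0.0]
    k_creat:      [0.1792, 0.0]
    k_NB_G:       [6.4953e5, 1.0063e6]
    k_NB_Gd:      [5.5590e4, 9.0741e4]
    k_NK_IL8:     [4.5302e4, 2.6386e4]
    k_NM_IL8:     [2.9804e3, 6.6655e3]
    k_NK_NM_IL8:  [5.9631, 16.7691]
    k_IL8_Pd:     [1.2841e4, 1.4198e4]
    k_filter_off: [0.1407, 0.0328]
init:
  survivor:
    P: 1000.0
    N_B: 4.4
    C_creat: 91.5455
  nonsurvivor:
    P: 1000.0
    N_B: 5.06
    C_creat: 102.4
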