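# Paroxetine template: CYP2D6 + CYP3A4 metabolism, unspecific hepatic
# clearance, glomerular filtration, and mechanism-based auto-inhibition of
# CYP2D6 and CYP3A4.  The CYP2D6 kcat is the optimized AS = 2 baseline;
# all other kinetic values are calibration placeholders chosen so that
# CYP2D6 dominates clearance and the auto-inhibition measurably compresses
# exposure ratios between activity scores (they reproduce no published
# appendix values).
name: paroxetine
em_reduction: 0.35
compounds:
  - name: paroxetine
    molecular_weight: 329.37
    fraction_unbound: 0.05
    lipophilicity: 3.0
    blood_plasma_ratio: 1.0
    partition_coefficients:
      lung: 15.0
      liver: 10.0
      gut: 8.0
      kidney: 8.0
      adipose: 10.0
      muscle: 4.0
      rest: 4.0
processes:
  - name: PAR_CYP2D6
    kind: michaelis_menten
    compound: paroxetine
    enzyme_label: CYP2D6
    kcat: 4.09      # 1/min, optimized AS = 2 baseline
    km: 1.0         # µmol/L
  - name: PAR_CYP3A4
    kind: michaelis_menten
    compound: paroxetine
    enzyme_label: CYP3A4
    kcat: 0.253
    km: 5.0
  - name: PAR_CLhep
    kind: first_order_hepatic
    compound: paroxetine
    cl_linear: 28.0   # L/h on unbound liver concentration
  - name: PAR_GFR
    kind: glomerular_filtration
    compound: paroxetine
inactivations:
  - name: PAR_MBI_CYP2D6
    inhibitor_compound: paroxetine
    target_enzyme_label: CYP2D6
    kinact: 2.0     # 1/h
    ki: 2.0         # µmol/L
  - name: PAR_MBI_CYP3A4
    inhibitor_compound: paroxetine
    target_enzyme_label: CYP3A4
    kinact: 2.0
    ki: 2.0
standard_regimen:
  route: oral_tablet
  dose: 40.0        # mg; 20 mg is an equally supported steady-state choice
  n_doses: 28
  interval: 24.0
  ka: 1.0
  lag: 0.5
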