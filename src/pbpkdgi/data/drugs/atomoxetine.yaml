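# Atomoxetine template: CYP2D6 + CYP2C19 metabolism and glomerular
# filtration.  The CYP2D6 kcat is the optimized AS = 2 baseline; CYP2C19
# and distribution values are calibration placeholders sized so that CYP2D6
# carries ~90% of oral clearance in AS = 2 populations.
name: atomoxetine
em_reduction: 0.30
compounds:
  - name: atomoxetine
    molecular_weight: 255.35
    fraction_unbound: 0.013
    lipophilicity: 3.9
    blood_plasma_ratio: 1.0
    partition_coefficients:
      lung: 2.0
      liver: 4.0
      gut: 3.0
      kidney: 3.0
      adipose: 2.0
      muscle: 1.5
      rest: 1.5
processes:
  - name: ATO_CYP2D6
    kind: michaelis_menten
    compound: atomoxetine
    enzyme_label: CYP2D6
    kcat: 103.82    # 1/min, optimized AS = 2 baseline
    km: 2.0
  - name: ATO_CYP2C19
    kind: michaelis_menten
    compound: atomoxetine
    enzyme_label: CYP2C19
    kcat: 12.1
    km: 5.0
  - name: ATO_GFR
    kind: glomerular_filtration
    compound: atomoxetine
inactivations: []
standard_regimen:
  route: oral_tablet
  dose: 40.0
  n_doses: 56
  interval: 12.0
  ka: 1.5
  lag: 0.25
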