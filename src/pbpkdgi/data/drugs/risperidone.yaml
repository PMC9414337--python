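# Risperidone parent-metabolite template: risperidone is converted to the
# active metabolite 9-hydroxyrisperidone and to other metabolites, each via
# CYP2D6 and CYP3A4; 9-hydroxyrisperidone is cleared by an unspecific
# hepatic process.  CYP2D6 kcat values are the optimized AS = 2 baselines;
# CYP3A4 and metabolite clearance values are calibration placeholders sized
# so that the active moiety (parent + metabolite) partially buffers CYP2D6
# genotype effects.
name: risperidone
em_reduction: 0.36
compounds:
  - name: risperidone
    molecular_weight: 410.49
    fraction_unbound: 0.10
    lipophilicity: 2.5
    blood_plasma_ratio: 1.0
    partition_coefficients:
      lung: 4.0
      liver: 6.0
      gut: 4.0
      kidney: 4.0
      adipose: 3.0
      muscle: 2.0
      rest: 2.0
  - name: 9-hydroxyrisperidone
    molecular_weight: 426.48
    fraction_unbound: 0.23
    lipophilicity: 2.0
    blood_plasma_ratio: 1.0
    partition_coefficients:
      lung: 1.0
      liver: 2.0
      gut: 2.0
      kidney: 2.0
      adipose: 1.0
      muscle: 1.0
      rest: 1.0
processes:
  - name: RIS_CYP2D6_9HR
    kind: michaelis_menten
    compound: risperidone
    enzyme_label: CYP2D6
    kcat: 3.19      # 1/min, optimized AS = 2 baseline (risperidone -> 9-OH)
    km: 5.0
    product_links:
      - ["9-hydroxyrisperidone", 1.0]
  - name: RIS_CYP2D6_other
    kind: michaelis_menten
    compound: risperidone
    enzyme_label: CYP2D6
    kcat: 1.94      # 1/min, optimized AS = 2 baseline (risperidone -> other)
    km: 5.0
  - name: RIS_CYP3A4_9HR
    kind: michaelis_menten
    compound: risperidone
    enzyme_label: CYP3A4
    kcat: 0.102
    km: 5.0
    product_links:
      - ["9-hydroxyrisperidone", 1.0]
  - name: RIS_CYP3A4_other
    kind: michaelis_menten
    compound: risperidone
    enzyme_label: CYP3A4
    kcat: 0.102
    km: 5.0
  - name: RIS9HR_CLhep
    kind: first_order_hepatic
    compound: 9-hydroxyrisperidone
    cl_linear: 11.7   # L/h on unbound liver concentration
inactivations: []
standard_regimen:
  route: oral_tablet
  dose: 2.0
  n_doses: 56
  interval: 12.0
  ka: 1.5
  lag: 0.25
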