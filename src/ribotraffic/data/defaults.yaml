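# Literature-derived default parameters for the yeast-calibrated model.
# Each value is a documented modelling choice; override any of them via the
# run configuration file or CLI flags.

kinetics:
  # Ribosome footprint in codons (~30 nt protected fragment).
  ribosome_width_codons: 9
  # Target mean elongation (hopping) rate at full charging, codons/s
  # (standard textbook estimate for S. cerevisiae, ~10 aa/s).
  mean_hopping_rate: 10.0
  # Termination is not rate limiting; keep well above all hopping rates.
  termination_rate: 50.0

cell:
  # Reference totals for a typical yeast cell, used only through the
  # tRNA-per-codon ratio and the effective-volume scaling.
  codons: 1.3e7
  trnas: 2.9e6
  volume_litres: 4.2e-14   # 42 um^3

enzymes:
  # Aminoacyl-tRNA synthetases, treated as a single averaged enzyme.
  kcat: 10.0               # turnover number, 1/s
  km_molar: 3.0e-7         # Michaelis constant, 0.3 uM
  enzymes_per_trna: 0.18   # synthetase molecules per tRNA molecule

schedule:
  burn_in: 200.0           # simulated seconds discarded as transient
  measure: 400.0           # simulated seconds of steady-state measurement
  n_blocks: 5              # block averaging for standard errors
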