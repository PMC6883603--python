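# ACMG-AMP 2015 combining rules, data-driven so refined tables can drop in.
# Each row fires when the per-strength code counts meet every "min" threshold
# (and stay within any "max"). Pathogenic-side strengths: very_strong, strong,
# moderate, supporting. Benign-side strengths: standalone, strong_benign,
# supporting_benign. Classification takes the strongest fired row per side.
pathogenic_rows:
  - {id: P1a, result: Pathogenic, min: {very_strong: 1, strong: 1}}
  - {id: P1b, result: Pathogenic, min: {very_strong: 1, moderate: 2}}
  - {id: P1c, result: Pathogenic, min: {very_strong: 1, moderate: 1, supporting: 1}}
  - {id: P1d, result: Pathogenic, min: {very_strong: 1, supporting: 2}}
  - {id: P2, result: Pathogenic, min: {strong: 2}}
  - {id: P3a, result: Pathogenic, min: {strong: 1, moderate: 3}}
  - {id: P3b, result: Pathogenic, min: {strong: 1, moderate: 2, supporting: 2}}
  - {id: P3c, result: Pathogenic, min: {strong: 1, moderate: 1, supporting: 4}}
  - {id: LP1, result: Likely Pathogenic, min: {very_strong: 1, moderate: 1}}
  - {id: LP2, result: Likely Pathogenic, min: {strong: 1, moderate: 1}, max: {moderate: 2}}
  - {id: LP3, result: Likely Pathogenic, min: {strong: 1, supporting: 2}}
  - {id: LP4, result: Likely Pathogenic, min: {moderate: 3}}
  - {id: LP5, result: Likely Pathogenic, min: {moderate: 2, supporting: 2}}
  - {id: LP6, result: Likely Pathogenic, min: {moderate: 1, supporting: 4}}
benign_rows:
  - {id: B1, result: Benign, min: {standalone: 1}}
  - {id: B2, result: Benign, min: {strong_benign: 2}}
  - {id: LB1, result: Likely Benign, min: {strong_benign: 1, supporting_benign: 1}}
  - {id: LB2, result: Likely Benign, min: {supporting_benign: 2}}
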