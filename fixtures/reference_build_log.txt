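reference model build log
=========================

Published-table inconsistencies handled at build time:
- teledermatology out-of-pocket mean prints 12.4 but conventional 16.3 plus incremental -4.1 gives 12.2; the calibrated profile uses 12.2 so the incremental column (total 32.5) is reproduced exactly.
- published teledermatology total prints 387.0; the category constants used here sum to 386.5 (= 354.0 + 32.5).
- preventable proportion: point value 0.20 as printed, distribution beta_integral(4, 19) with mean 4/19 = 0.2105; GP diagnosis-and-treatment mean 18.4 is reproduced at the distribution mean (4/19 x 87.6 = 18.44), not at the point value (0.20 x 87.6 = 17.52).
- consultation-shortening distribution printed as beta(n=3, r=30) is transposed to beta_integral(r=3, n=30), mean 0.10, matching the stated 10% shortening.

Mechanistic point values vs published category means (mechanistic formulas kept; calibrated profile is the numeric surface):
- teledermatology investment: mechanistic 2.32 vs published 1.6
- teledermatology gp: mechanistic 70.82 vs published 85.5
- conventional gp: mechanistic 20.25 vs published 21.3
- teledermatology dermatologist: mechanistic 282.20 vs published 241.0
- conventional dermatologist: mechanistic 285.30 vs published 269.1
- teledermatology out_of_pocket: mechanistic 17.38 vs published 12.4
- conventional out_of_pocket: mechanistic 21.18 vs published 16.3
- teledermatology employer: mechanistic 40.47 vs published 46.2
- conventional employer: mechanistic 47.39 vs published 47.3
- incremental total: mechanistic 39.06 vs published 32.5

Investment sub-components (camera 0.8 / website 0.16 / training 0.6) are not recoverable from the published primitives (camera 175/180 = 0.97, website 40000/900000 = 0.044, training 1.30); logged, not forced.
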