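# Methods

## Problem setting

In-vitro digestion of a synthetic substrate polypeptide by purified 20S
proteasomes produces both contiguous (non-spliced) fragments and
*cis*-spliced peptides, in which two non-contiguous fragments of one
substrate molecule are ligated — in substrate N→C order (normal) or
inverted (reverse). Identification against such a substrate must search a
database of *all* theoretically possible products, and must defend spliced
identifications against isobaric contiguous alternatives. The package
implements that workflow — candidate enumeration, fragment theory, MS2
annotation and discrimination, hit filtering, and XIC-based kinetics
quantification — and ships a seeded simulator so the whole chain is
testable without instrument data.

## Enumeration model

A substrate of length N with numbering offset o (protein coordinate of its
first residue) yields:

- non-spliced products: every substring with length in `[min_len, max_len]`
  (defaults 5-25, bracketing HLA class I ligand lengths; the true search
  window of historical studies is not fixed by any public parameter set, so
  the bound is an explicit, configurable design choice);
- normal *cis* products R1+R2 with reactant intervals `[a1,b1]`, `[a2,b2]`,
  `a2 ≥ b1+2` — at least one skipped residue, since a zero gap reproduces
  the contiguous case;
- reverse *cis* products with `b2 ≤ a1−1` — adjacency is allowed but
  overlap is not, because one molecule cannot contribute a residue twice.

Products identical in sequence are merged with all generating origins
retained (`5-6/8-14;5-7/9-14;...`). Trans-splicing (reactants from two
substrate molecules) is out of scope. Classification of a query sequence is
hierarchical: substring ⇒ `nonspliced`; otherwise any cis event ⇒
`spliced_only`; else `not_producible`.

Variable modifications (M oxidation +15.994915 Da, N/Q deamidation
+0.984016 Da) are expanded after sequence-level deduplication, up to
`max_variable_mods` sites per peptidoform (default 2).

## Mass and fragment arithmetic

Monoisotopic throughout. Neutral mass = Σ residue masses + H2O; precursor
m/z = (M + z·1.0072765)/z. Fragment series: b (prefix + z protons),
a (b − CO, 27.994915 Da), y (suffix + H2O + z protons); NH3-loss variants
subtract 17.026549/z. Defaults generate b/a/y, NH3 loss, charges 1-2; H2O
loss exists behind a config flag but is off by default (only the ammonia
loss appears in the reference annotation style). b1/a1/y1 are generated;
immonium ions are not. Key identities enforced by tests: b_i + y_{n−i}
(z=1) = M + 2·proton; a_i = b_i − CO; doubly charged m/z = (singly charged
+ proton)/2.

## Annotation, discrimination, surrogate score

Peak↔ion assignment is greedy: ions in ascending theoretical m/z, each
taking the nearest unused peak within the tolerance (ppm or Da; presets
"QE" = 6/20 ppm MS/MS2 and "Exploris" = 5 ppm/0.02 Da). This is
deterministic and order-independent for peaks separated by more than two
windows.

For two candidates, an ion of A is *mass-shared* if any theoretical ion of
B lies within tolerance, else *diagnostic* for A. For the KRAS pair at z=1
b/y this gives diagnostics {b5, b6, b8, y1, y3, y4} each side and shared
{b1, b2, b3, b4, b7, y2, y5, y6, y7, y8} — exactly the cut points where the
prefix/suffix residue compositions differ. A spectrum's verdict is the
candidate with strictly more observed diagnostic ions; ties are ambiguous.
RT resolution uses strict inequality: |ΔRT| > rt_tol.

The match score is a documented surrogate for proprietary search-engine ion
scores: −10·log10 of the binomial tail P(X ≥ k) for k matched of m
theoretical ions, with per-ion random-match probability estimated from peak
density (peaks × mean window width / m/z span, clamped to (0,1)). Empty
spectra and zero-match annotations score 0. Downstream filtering treats the
score column as opaque, so engine-produced scores can be imported via CSV.

## Identification filter

Per scan: the top-scoring hit must be unique (ties reject the scan); it
must have ion score ≥ 20 and q-value ≤ 0.05 (inclusive cutoffs). A spliced
top hit additionally requires Δ = 100·(S_top − S_other)/S_top ≥ 10% against
the best other spliced hit and ≥ 30% against the best non-spliced hit; a
missing competitor passes vacuously. The two delta conditions combine with
AND by default (the stricter reading; OR is configurable). The delta
denominator is the top score — the usual relative delta-score convention.
Scans whose top score is ≤ 0 with competitors present are rejected outright
(the percentage is undefined). q-values are consumed, not computed; a
target-decoy helper (decoy counting) is provided for fully synthetic runs.

## XIC quantification

Extraction sums intensities within an inclusive m/z window per MS1 scan
(default 421.275-421.875, covering the doubly charged isotope envelope of
both KRAS targets). Peak calling: the apex is the highest local maximum
within `rt_tol` (default 0.5 min) of the synthetic-standard reference RT;
SNR is apex over the median of the trace outside the integration bounds
(floored at machine epsilon); presence requires SNR ≥ `snr_min`
(default 3 — "biologically significant" needs a quantitative proxy).
Integration: trapezoidal rule with zero baseline over the contiguous
region where intensity ≥ 5% of the apex. These defaults replace the
undocumented parameters of commercial quantification toolboxes and are all
configurable. Technical replicates are combined by mean; biological
replicates stay separate.

With the default simulator geometry (Gaussian peaks, σ = 0.1 min, scan
spacing 0.02 min) the 5%-of-apex bounds clip about 0.06% of a Gaussian's
analytic area, so the 2% recovery tolerance is dominated by noise, not by
the integration rule.

## Synthetic-data model

All generators are pure functions of (config, seed); bundle runs derive
per-run sub-seeds from the global seed and the run label via a 32-bit
polynomial hash reduced mod 2³¹−1.

- **Digestion**: biphasic first-order substrate survival
  S(t) = exp(−k1·min(t,τ) − k2·max(0, t−τ)) — proteasome catalytic dynamics
  change over time, so a single rate is not assumed. Defaults: k1 = ln(4)/4
  ≈ 0.3466 /h (a quarter of the substrate remains at 4 h), τ = 4 h,
  k2 = k1/2 (≈ 1.6% remains at the 20 h endpoint, matching the expectation
  that nearly all substrate is consumed there). Product amounts follow
  mass-balance-flavoured kinetics product_i(t) = α_i·(1 − S(t)), one
  amplitude per product; amplitudes are unconstrained because products are
  fragments, not a partition of the substrate.
- **MS2**: each theoretical ion detected with probability p (default 0.8)
  at m/z·(1+ε), ε ~ N(0, σ ppm) (default 5 ppm), lognormal intensity;
  uniform noise peaks over the fragment m/z range.
- **MS1 runs**: each peptide contributes a Gaussian elution profile at its
  precursor m/z whose RT-integral equals amount × area scale; a uniform
  noise floor sits inside the standard extraction window so extracted
  traces carry a realistic baseline. Default reference RTs place the
  spliced/non-spliced pair 2 min apart (RT-resolved, as observed on real
  gradients); a co-eluting stress configuration (ΔRT = 0.2 min) is
  provided.
- **Design**: 3 biological × 5 time points (0, 1, 2, 3, 4 h) × 3 technical
  = 45 kinetics runs, plus per-replicate 20 h endpoints, a no-proteasome
  control and one synthetic-standard run per target.
- **Hit tables**: per scan, the true peptide at rank 1 with uniform score
  and q-value, competitors at controlled relative score gaps, so the filter
  outcome is known in closed form for every scan.

What the simulator does *not* emulate — isotope envelopes, profile-mode
peaks, chromatographic tailing and drift, interfering near-isobaric
background peptides, instrument duty-cycle effects — bounds what a green
test establishes: correctness of the computational chain against planted
ground truth, not instrument-level performance on real digests.

## Numerical choices and edge cases

- Residue masses fixed to standard monoisotopic values at 6 decimals, as
  data (pinned in tests).
- m/z printed with 5 decimals, areas with 6 significant figures, for stable
  text outputs.
- Inclusive bounds everywhere a printed convention exists (m/z window,
  score/q/delta cutoffs).
- Empty peptide mass = water; fragmentation requires length ≥ 2; empty
  spectra annotate to zero matches and score 0.
- The MGF dialect reads TITLE/PEPMASS/CHARGE/RTINSECONDS, accepts "2+"
  charges, converts RT to minutes; scan-series CSV preserves empty scans
  with a zero-intensity sentinel row.

## Known limitations

No vendor RAW or mzML support (MGF and CSV are the interchange formats);
no deisotoping or charge deconvolution; no chromatographic alignment across
runs; no modelling of proteasome cleavage-site or splicing-site preference;
the surrogate score is not calibrated against any commercial engine's score
scale — only its rank behaviour matters to the filter.
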