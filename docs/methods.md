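# Methods

## Model and procedure

A symbolic sequence of length N over {A, C, G, T} (or the 20 amino
acids) is converted to numeric series in one of two ways.

**Binary indicators (multichannel mapping).** One channel per symbol,
u<sub>α,n</sub> ∈ {0, 1} marking presence of α at position n. Each
channel is transformed independently with the unnormalized forward DFT
U<sub>α</sub>(j) = Σ<sub>n</sub> u<sub>α,n</sub> exp(−2πi j n / N), and
the combined spectrum is S(j) = Σ<sub>α</sub> |U<sub>α</sub>(j)|².
On unambiguous input the channels partition the positions, so the
full-grid combined power sums to N² (Parseval), a property the tests
exploit. The combined spectrum is invariant under cyclic shifts and
under reverse complement (reversal conjugates each transform;
complementation permutes channels A↔T, C↔G and leaves the sum
unchanged) — which is also why minus-strand CDS are partitioned as
forward-strand text.

**Flexibility profile.** Each nearest-neighbour dimer step is replaced
by its elastic constant k (eV/nm²), giving a single series of length
M = N − 1. Ten unique constants are shipped (ApA 2.40, ApC 2.56,
ApG 2.25, ApT 1.83, CpA 3.44, CpC 2.06, CpG 2.74, GpA 2.80, GpC 3.36,
TpA 2.42, range [1.83, 3.44]); the remaining six dimers take the value
of their reverse complement (TpT→ApA, GpT→ApC, CpT→ApG, TpG→CpA,
TpC→GpA, GpG→CpC). This is the standard nearest-neighbour uniqueness
convention under strand symmetry, and it is what makes the flexibility
profile of a reverse complement equal the reversed profile (property-
tested). The profile is mean-centered before transforming by default:
the mean (~2.4) would otherwise leak a large DC skirt over the
low-frequency bins of interest.

**Why aliases arise.** A tandem repeat of period p with one (or few
consecutive) occurrences of a symbol per unit turns that symbol's
channel into a rectangle train: R repeats of m consecutive ones in a
p-length unit. Its power at the comb frequency k/p has the closed form

    P(k) = R² · (sin(π k m / p) / sin(π k / p))²

by summing the geometric phase series. For m = 1 this is R² at *every*
k — the full comb — although the only true period present is p. The
function `rect_train_power_oracle` implements this closed form
independently of any FFT and anchors the spectra tests at relative
tolerance 1e-9 over p = 2..30, m = 1..p, R ∈ {5, 80}.

**Comb detection.** Overtone powers are read off at the comb
frequencies k/p for k = 1..⌊p/2⌋ (Nyquist limit), taking the maximum
over bins within ±1 bin of k/p·N — generic peak search is deliberately
avoided; the bin tolerance absorbs transform lengths not divisible by
p. The DC bin is always excluded. An overtone is *detected* when its
power reaches a fraction (default 0.2) of the largest overtone power.
Detection is therefore invariant under overall spectrum scaling and
weakly shrinking in the threshold.

**Alias classification.** The same sequence is scored at the same
period and threshold under (a) the combined binary spectrum and (b) the
centered flexibility spectrum. Losing ≥ 2 detected overtones under the
smooth mapping yields the verdict `alias-dominated`; zero binary
detections is `no-comb`; otherwise `consistent-periodicity`. The margin
of 2 is exposed as a parameter because a one-overtone difference is
within threshold sensitivity.

**Position-dependent power.** The power at a single monitored frequency
f is evaluated in windows of size w (default 1000 nt, the scale at
which chromosome-extremity repeat blocks were localised), with phase
referenced to the window start so values are translation-comparable.
Because monitored comb frequencies like k/21 are generally not bins of
a 1000-point window, the exact frequency is evaluated by direct
summation (Goertzel-style); a `snap_to_bin` mode rounds to the nearest
bin l/w for comparison. Windows are non-overlapping by default
(step = w), configurable.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| window w | 1000 | nt | localisation scale for position-dependent power |
| flank | 4000 | nt | chromosome-extremity region holding the repeat blocks |
| monitored period p | 21 | nt | the repeat periodicity under study (18 for the coding-region comb) |
| detection threshold | 0.2 | relative | calibrated on the 80×21 constructions: the 10-nt-run unit keeps exactly one peak (strongest non-fundamental overtone ≈ 11%), the 1-nt-run unit keeps all ten |
| comb tolerance | 1 | bins | absorbs transform lengths not divisible by p |
| alias margin | 2 | overtones | one overtone is within threshold sensitivity |
| background AT fraction | 0.8 | — | extreme AT richness of the *P. falciparum* genome |

## Synthetic data: what it emulates, what it does not

The generators produce (i) rectangle-train repeats (R copies of m run
symbols + p−m fill symbols), (ii) CA_n microsatellites (period n+1),
(iii) tandem arrays of the 26 consensus units reported at
*P. falciparum* chromosome extremities (shipped verbatim as a FASTA
resource, including the 20-nt units flagged `short_unit=yes` whose
printed length disagrees with the nominal 21-nt periodicity; the
discrepancy is preserved, not corrected, and the shipped repetition
counts are external-tool metadata, never asserted), and (iv) i.i.d.
AT-rich backgrounds (A = T = 0.4, C = G = 0.1) with repeat blocks
planted near an extremity. All entry points are seeded.

Real chromosomes differ in ways the generators do not model: repeats
are inexact (substitutions, indels, variable unit copies), the
background is not i.i.d. (isochores, low-complexity runs), and
annotation boundaries interleave with repeats. A green test therefore
establishes that the spectral machinery and the alias logic are
correct on exactly periodic and i.i.d.-background inputs — not that
verdicts on real genomes are error-free. In particular, the flexibility
mapping only de-aliases sequences whose dimer profile is genuinely
smoother than the indicator channels; for an artificial unit of one C
in a poly-A background, the dimer profile is itself spike-like (two
non-AA steps per unit) and the flexibility comb persists, so the
classifier returns `consistent-periodicity` for that construction.
This is a property of the mapping, not a defect of the detector.

## Numerical choices

- Unnormalized forward DFT, power = |U|², no 1/N scaling: published
  spectra of this kind are in arbitrary units, and the choice keeps
  closed forms integer-valued for binary inputs.
- Full-grid conjugate symmetry is asserted before truncating to the
  half grid j = 0..⌊N/2⌋; only the half grid is exposed.
- Comb powers tie-break by taking the maximum within the bin tolerance;
  an all-zero comb detects nothing (no 0/0 relative powers).
- Ambiguity codes (N etc.) are retained, flagged, and map to all-zero
  indicator columns, preserving genome length. In flexibility encoding
  they NaN-mask the adjacent steps by default (`strict` raises);
  spectra refuse NaN, so masked profiles are split into unambiguous
  segments first (`split_on_ambiguity`).
- CDS partition merges overlapping intervals and concatenates each
  class into one series per sequence (one spectrum per chromosome per
  class); junction artifacts of concatenation are accepted — they are
  O(number of regions) against O(length) of in-region signal.
- GFF3 is converted from 1-based inclusive to the internal 0-based
  half-open convention at the reader boundary; BED passes through.

## Known limitations

- No tapering, Welch averaging or significance testing of peaks; comb
  detection is a relative-power rule, not a statistical test.
- The alias verdict compares detection counts only; it does not model
  how much overtone power *should* survive a smooth re-encoding.
- Windowed tracks use a rectangular window; spectral leakage between
  nearby comb frequencies is not suppressed.
- Protein analysis covers the 20-channel encoding and spectra; no
  amino-acid property mapping is shipped (the flexibility-table format
  admits user-supplied dinucleotide tables only).
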