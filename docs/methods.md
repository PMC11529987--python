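# Methods

This note documents the models, conventions, and numerical choices behind
`tcrspec`, and what the synthetic-data generators do and do not emulate.

## Normalization

Raw reporter readouts (fraction of GFP⁺ reporter cells after TCR
engagement) and ⁵¹Cr-release counts are normalized linearly between two
anchor conditions:

    specific value (%) = (test − min) / (max − min) × 100.

The minimum anchor is the no-stimulus condition (media alone, or
spontaneous release); the maximum anchor depends on assay design and is an
explicit input recorded in every output: the cognate-peptide-pulsed
condition (dose-response and library scans), PMA-ionomycin (reporter
positive control), or detergent lysis (release assays). Values above 100%
are trimmed to 100 and negative values adjusted to zero; both events are
flagged. Trimming is applied **per replicate, before averaging** — the
source protocol does not state the order, and per-replicate trimming is the
reading most consistent with per-peptide trimming of library readouts.
Replicate spread is the sample (n−1) standard deviation; with one replicate
the spread is reported as 0 rather than NaN.

Consequences worth knowing: the map is monotone in the test readout,
invariant under positive affine rescaling of the raw units, and pins the
anchors exactly to 0 and 100.

## Dose-response fitting (EC₅₀)

The four-parameter logistic is fit in log₁₀-concentration space:

    y(c) = bottom + (top − bottom) / (1 + 10^{ hill · (log₁₀EC₅₀ − log₁₀ c) }),

algebraically identical to `bottom + (top − bottom)/(1 + (EC₅₀/c)^hill)`.
Fitting uses `scipy.optimize.curve_fit` (bounded trust-region least
squares) with a deterministic initialization: hill = 1, top/bottom from the
data extremes, and EC₅₀ at the tested concentration whose response is
nearest half-maximal. Bounds: log₁₀EC₅₀ within two decades of the tested
range (a fit outside the tested range is flagged `extrapolated`), hill in
[0.1, 10], top in [0, 120]%, bottom in [−20, 100]%. Top and bottom are
left free (bounded) rather than fixed at 100/0, since normalized data do
not always reach their anchors; the bounds keep the fit in the physically
meaningful band. A series must have ≥ 5 distinct concentrations spanning
≥ 2 decades; an all-equal response vector is a flat-curve error (EC₅₀
undefined), and optimizer failure is reported via `converged=False`, never
silently. The fit is scale-equivariant: multiplying all concentrations by
c multiplies the fitted EC₅₀ by c.

Functional avidity differences are Δlog₁₀EC₅₀ = log₁₀(EC₅₀_b/EC₅₀_a).
CD8-coreceptor dependence is classified from the CD8⁻ vs CD8⁺ shift:
< 0.5 log₁₀ independent, 0.5–1.0 partial, > 1.0 dependent. These
boundaries are a package convention (recorded in every result); they
reproduce the qualitative labels observed experimentally, where
coreceptor-dependent TCRs shift by 1–2 decades and independent ones
barely move.

## Kill-curve KT₅₀

Viability indices (total fluorescence intensity or impedance cell index,
normalized to 1 immediately after effector addition) are fit to a
single-exponential decay `index(t) = exp(−k t)`; KT₅₀ = ln 2 / k. The
single-exponential was chosen as the primary model because it matches
normalized monotone decay and admits a closed-form oracle for testing. A
fitted curve that never reaches 0.5 within the observation window yields a
censored result (`> t_max h`); an increasing index (target outgrowth) is
censored with an `outgrowth` flag. Initialization is the slope of a
log-linear regression (indices floored at 10⁻⁶ for the logarithm), and k is
bounded below at 0.

## X-scan libraries and recognition motifs

An X-scan library substitutes each position of the cognate n-mer with the
19 other canonical residues (19 n peptides; 190 for a decamer). The
Ala/Gly library substitutes alanine at every position, with glycine at
positions whose cognate residue is already alanine — the standard
alanine-scanning convention.

Normalized activities populate an n × 20 matrix with cognate cells pinned
to 100 (the cognate peptide is the 100% anchor). The recognition motif
takes, at each position, the set of residues with activity **≥** the
threshold (inclusive; default 50%) — "minimum 50%" reads naturally as
inclusive, and the exact-boundary case is tested. The cognate residue is
always a member. Raising the threshold can only shrink position sets, and
a peptide matches the motif iff every one of its residues clears the
threshold at its position.

Logo letter heights are **linear in specific activity** (activity/100),
not information bits: the height should depict reporter activation
directly, and only residues at or above the threshold appear. Positions
are numbered P1..Pn from the N-terminus; mapping to source-protein residue
numbers is metadata, not semantics.

## Proteome scanning and candidate curation

Motifs compile to PROSITE-style patterns: a plain letter for singleton
sets, `x` for fully tolerant positions, bracketed alphabetical classes
otherwise; compilation and parsing round-trip. Scanning reports **every**
window whose residues all lie in the per-position sets — overlapping
matches each reported, in deterministic (protein id, start) order. The
implementation uses per-position byte-indexed lookup tables over numpy
views; its contract is defined (and tested, on > 10⁶ residues) against a
brute-force all-windows oracle. Non-canonical residues in proteome
sequences (X, U, B, ...) never match any class and never raise — real
proteome releases contain them. Splice-isoform expansion is out of scope.
Candidate lists depend on the proteome release, so outputs record the
proteome file's SHA-256.

Curation keeps noncognate matches with predicted pHLA-binding EC₅₀ ≤ 500 nM
(inclusive — a prediction of exactly 500 nM is retained); excluded matches
carry an explicit reason, and windows identical to the cognate epitope are
flagged separately, never counted as noncognate candidates. Predictions
normally come from an external predictor via a generic TSV
(peptide, allele, affinity_nM); the package never invokes such a tool. A
built-in anchor scorer (`builtin-anchor-pwm`) ships so the pipeline runs
end to end without one: it rewards the HLA-A3-superfamily anchors
(P2 ∈ {L, I, V, M, T, S}, C-terminal K/R — the basic C-terminus its
epitopes carry experimentally) and maps the score monotonically to a
pseudo-EC₅₀. It is a deterministic stand-in, not a trained binding model;
candidate lists derived from it are illustrative only.

## pHLA copies per cell

For each injection, moles of analyte = (light area / heavy area) × spike
amount; duplicate injections are averaged on the ratio scale (the
combination rule is a package choice; per-sample reference values do not
state one). The mean is divided by the injected fraction of the enriched
sample — a generalization of "doubling" when half the sample is injected —
then converted to molecules with N_A = 6.02214076 × 10²³ mol⁻¹ and divided
by the input cell count. The result depends only on the area *ratio*, is
linear in it, and inversely linear in cell count. Abundance classes
(low/intermediate/high) use explicit, configurable bounds (defaults 35 and
75 copies/cell) because published per-cell-line ranges overlap; the bounds
are recorded with every classification. Raw spectra and chromatogram
integration are upstream of this package; it consumes peak-area tables.
Identity confirmation compares apex retention times (tolerance 0.2 min by
default) and, when per-fragment intensities are supplied, the fragment
rank order.

## Synthetic data

Generators emulate the study designs so that every stage has inputs with
known truth: 4PL responses with additive Gaussian noise (default sd 5
points, clipped to [0, 100]) on a half-log titration from 10 μM to 1 pM
(15 concentrations — half-log spacing over the full stated titration
range); X-scan readouts drawn uniformly from (60, 100) for tolerated and
(0, 40) for rejected residues, ranges that straddle the 50% cutoff so
motif recovery is exact by construction (overlapping ranges void the
guarantee, deliberately); random proteomes with i.i.d. residues (uniform
1/20 background by default, keeping incidental-match expectations
closed-form: E[matches] = windows × Π|setᵢ|/20) and planted,
non-overlapping pattern realizations at recorded coordinates; PRM areas
back-computed from a true copies/cell with median-1 lognormal noise per
injection; and exponential kill curves with additive noise, index(0)
forced to 1.

Determinism: one global seed, with per-generator substreams derived by
hashing the generator id into the seed sequence — adding a generator never
perturbs another's draws; identical seeds give byte-identical files. Every
generator writes a JSON truth sidecar, and recovery tests read truth only
from the sidecar.

What the generators do **not** emulate: instrument artifacts (flow gating,
carryover, chromatographic drift), correlated replicate noise, non-uniform
amino-acid composition and homology structure of real proteomes (planted
matches are the only non-random signal), biphasic killing kinetics, and
peptide synthesis/purity effects. Passing recovery tests therefore
demonstrates correctness of the computations under the stated noise
models, not robustness to every failure mode of real data.

## Pipeline

Stages (`xscan → motif → scan → filter`, plus independent `fit`, `quant`,
`kt50`) run in dependency order; inputs for all selected stages are
validated before any computation, all config problems are reported at
once, and a failing stage aborts the run with its name in the manifest.
The manifest records the config snapshot, SHA-256 of each input, package
version, timestamps, and per-stage row counts. Stage outputs are
byte-reproducible for identical config and inputs; the manifest's
timestamps are the only non-reproducible bytes. The bundled demonstration
uses a 300-protein synthetic proteome (~10⁵ residues) with 5 planted
matches; the scan itself handles proteome-scale input (tested against the
oracle at > 10⁶ residues).

## Known limitations

- The 4PL fit reports a single least-squares solution; no confidence
  intervals or model comparison (biphasic/Hill mixtures are out of scope).
- KT₅₀ assumes monotone exponential decay after normalization; partial
  killing that plateaus above 0.5 is reported as censored rather than fit
  with a floor parameter.
- The built-in affinity scorer is intentionally coarse (two anchor
  positions); real candidate curation should use a dedicated predictor's
  table.
- Motif extraction treats positions independently; epistatic effects
  between substitutions are invisible to a single-substitution scan by
  design.
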