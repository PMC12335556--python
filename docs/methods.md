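# Methods

## From trajectory to relaxation observables

The physical object connecting an MD trajectory to backbone ¹⁵N relaxation
is the second-order rotational autocorrelation function of each residue's
N–H bond unit vector,

    g(t) = ⟨ P2( v(t′) · v(t′+t) ) ⟩_t′ ,   P2(x) = (3x² − 1)/2 ,

averaged over all time origins t′. `spin_relax.compute_p2_acf` evaluates
this exactly (it equals the double loop over all origin pairs, tested to
1e-12) via FFT cross-correlations of the six independent components of the
outer product v⊗v, so a 10⁵-frame series costs seconds, not hours. Lags
run to half the series duration by default; beyond that the origin average
has too few terms to be useful, and the tail of the empirical ACF is noise
that the fit would otherwise chase.

The ACF is fitted to a sum of exponential decays on a fixed grid of
timescales, 100 points log-equidistant between 1 ps and 100 ns by default
(`build_timescale_grid`). The weights are solved by non-negative least
squares on the design matrix exp(−t_k/τ_i) (`scipy.optimize.nnls`); ACF
points are unweighted. No Σα = 1 constraint is imposed — g(0) = 1 keeps
the total weight near one for normalized input, and leaving the weights
free lets the fit absorb a sub-resolution initial decay. Because the grid
is heavily overcomplete the *individual* weights of a noisy fit are not
unique in any statistical sense; the derived quantities used downstream
(J(ω), T1/T2/NOE, τ_eff, binned timescale landscapes) are stable
functionals of the fit. For noiseless input built from grid timescales the
NNLS solution is the exact sparse representation (recovered to 1e-6 in the
tests).

Spectral densities use the convention

    J(ω) = Σ_i α_i · 2τ_i / (1 + (ωτ_i)²) ,

under which the d²_NH/20 dipolar prefactors in the rate expressions below
reproduce standard Redfield rates; this is cross-checked in the test suite
against an independently coded closed-form single-Lorentzian
implementation to 1e-10 relative. J is even, and magnitudes of frequency
combinations are used throughout (ω_N < 0 since γ_N < 0).

The rate expressions (dipolar ¹H–¹⁵N plus ¹⁵N CSA):

    1/T1 = (d²N_H/20)[J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H+ω_N)]
           + (Δσ ω_N)²/15 · J(ω_N)
    1/T2 = ½(d²N_H/20)[4J(0) + J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H) + 6J(ω_H+ω_N)]
           + (Δσ ω_N)²/90 · [4J(0) + 3J(ω_N)]
    hetNOE = 1 + σ_NH · γ_H T1 / γ_N ,

with d_NH = μ0 ħ γ_H γ_N / (4π ⟨r³_NH⟩). The cross-relaxation term
defaults to the standard sign, σ_NH ∝ 6J(ω_H+ω_N) − J(ω_H−ω_N); an
all-plus variant circulates in parts of the literature and is available as
`noe_sign_convention="paper_plus"`, but only the standard convention
reproduces the negative hetNOE values of highly flexible residues and the
extreme-narrowing limit 1 + ½γ_H/γ_N, so it is the default and the option
is flagged rather than silent. Chemical exchange (R_ex) contributions to
T2 on µs–ms timescales are outside the model by construction: nothing in a
sub-µs correlation function carries that information.

Default parameters: Δσ = −160 ppm, r_NH = 0.101 nm, N_H = 1, CODATA
γ_H = 2.6752218744·10⁸ and γ_N = −2.71261804·10⁷ rad s⁻¹ T⁻¹; all
overridable per `NMRParams`. Times are picoseconds at I/O boundaries
(trajectory convention) and seconds inside the physics.

τ_eff = Σ α_i τ_i is the plain weighted sum — the integral of the fitted
correlation function — *not* normalized by Σα. Note a practical
consequence of integrating the fit: positive noise excursions at long lags
cost the fit little residual but carry weight at large τ, so single short
trajectories can overestimate τ_eff; averaging correlation functions over
trajectories (as the selection step does) suppresses this.

## Ranking and selection

Each candidate simulation's predicted profile is compared with experiment
by the per-observable residue-averaged RMSD, in native units, matching
residues by author numbering; residues missing on either side are dropped
(with a logged count) and experimental errors are not used as weights.
Comparison numbers divide each RMSD by the per-observable minimum over
candidates, so the best candidate scores exactly 1.0. If the minimum is
exactly zero (noiseless planted truth) the zero-RMSD candidate scores 1.0
and the rest +inf — the only continuous extension consistent with "the
best scores 1.0". Selection keeps candidates whose three comparison
numbers are all strictly below the threshold (default 1.5); ties at the
threshold are rejected, the conjunction means a candidate best on one
observable can still be rejected on another, and the selection can be
empty, which `combine_ensemble` reports as an error advising threshold
review rather than silently returning nothing. The ensemble's observables
come from averaging the selected simulations' correlation functions per
residue *before* fitting — averaging the observables themselves would not
commute with the nonlinear map from ACF to rates.

## Ensemble characterization

R_g is the mass-weighted RMS distance from the center of mass, per frame;
histograms use Freedman–Diaconis binning by default. The backbone
orientation map averages dot products of unit vectors between consecutive
Cα atoms (an (N−1)×(N−1) matrix; +1 persistently parallel, −1
antiparallel, 0 decorrelated). Minimum-distance maps take, per residue
pair, the minimum over all atom pairs at 1 ns sampling intervals, then
average over time. PCA concatenates all trajectories, centers each frame,
superposes every frame on the concatenated mean structure with one Kabsch
fit (the mean of centered frames is a fixed point of the iteration to the
accuracy that matters here, so a single pass is used and the procedure is
seed-free), diagonalizes the 3N×3N Cα covariance, and projects each
trajectory onto PC1/PC2. Global rigid-body motion therefore contributes
nothing to the eigenvalues (tested to 1e-12).

## SAXS

Per-frame intensities are expected from an external scattering code (the
module parses crysol 3.x `.int`/`.fit` and generic `q I [sigma]` text;
frame subsampling conventionally takes every 1000th frame). Profiles on a
shared q grid are averaged pointwise, then fitted to experiment as
I_fit = scale·I_comp + offset using only points with 0.01 ≤ q ≤ 0.3 in the
input's q units; the computed profile is linearly interpolated onto the
experimental q points first. The model is linear in (scale, offset), so
the Levenberg–Marquardt iteration this fit is usually described with
converges to the ordinary least-squares solution; it is implemented in
closed form. RMSE is reported on the raw fitted intensities by default,
with the min-max-normalized variant also computed, since both conventions
appear in practice. A coarse Debye-formula calculator over Cα pseudo-atoms
(unit form factors, no solvent) exists so the tests are self-contained; it
is explicitly non-quantitative.

## Synthetic study conditions

The generators in `qebss.synthetic` define the conditions under which the
pipeline is exercised:

* **ACFs** are exact multi-exponentials with known weights, optionally
  with Gaussian noise at positive lags (g(0) stays exact).
* **The rotor** performs isotropic rotational diffusion: per step of
  length dt the unit vector rotates by sqrt(4·D_r·dt)·|N(0,1)| about a
  uniformly random axis perpendicular to itself, giving ⟨Δθ²⟩ = 4·D_r·dt
  and P2 decay with τ₂ = 1/(6·D_r). Valid while 4·D_r·dt ≪ 1 (a warning
  fires otherwise). The reference conditions — τ₂ = 5 ns observed for
  1 µs at 10 ps spacing — mimic a long production run at a typical frame
  saving frequency; a single such trajectory estimates τ_eff with ≈5–10%
  sampling scatter, which is what the 10% recovery tolerance reflects.
* **The selection fixture** builds five candidate simulations with
  two-component ACFs whose fast and slow timescales both follow per-
  simulation ladders (20 ps·2^s; 1.25 ns·2^s) and whose weight split
  varies along the five-residue sequence. Both components must vary: T1
  is non-monotonic in τ, and a slow-timescale ladder alone makes two
  candidates nearly degenerate in T1 at 600 MHz. The "experimental"
  table is the full forward model applied to the designated truth
  simulation plus 2% relative Gaussian noise — a typical reported
  experimental uncertainty — which is small against the ≥7% observable-
  space separation between candidates, so truth recovery is expected in
  every replicate.
* **The bead ensemble** joins two internally frozen bead clusters by a
  freely jointed linker redrawn each frame, emulating the
  folded-domains-plus-disordered-linker architecture of multidomain
  proteins. With single-bead domains it reduces to a freely jointed chain
  with ⟨R_g²⟩ = b²(n²−1)/(6n), the closed form used in the tests.

All generators draw from per-generator streams derived from the seed, so
outputs are bit-reproducible and adding a generator never perturbs
existing fixtures.

What these conditions do *not* emulate: real force-field dynamics,
anisotropic overall tumbling, amino-acid-specific chain statistics,
chemical exchange, and experimental artifacts beyond i.i.d. Gaussian
noise. Passing tests therefore demonstrate the correctness of the
computational chain and the selectivity of the protocol under known truth,
not force-field accuracy for any real protein.

## Numerical and design notes

* Frame skipping (`skip_time`) is a user decision; whether early R_g
  drift constitutes "clear conformational changes" warranting exclusion
  of an equilibration period is a judgement this package does not
  automate.
* The default N–H extraction mask excludes prolines and each chain's
  N-terminal residue — neither has a backbone amide ¹⁵N–H vector.
  Explicitly requesting such a residue is an error naming it.
* The timescale-landscape bin edges are a user parameter; published
  figures bin heterogeneously and no single canonical edge set exists.
* Averaging ACFs truncates to the shortest common lag range and requires
  matching residue IDs and lag spacing; no interpolation is performed.
  SAXS averaging likewise refuses mismatched q grids, while the
  computed-vs-experimental fit interpolates (computed onto experimental q)
  because those grids legitimately differ.
* Degenerate inputs fail loudly: all-NaN ACFs, empty selections, constant
  SAXS profiles (min-max undefined), zero total mass, coincident
  consecutive Cα atoms, thresholds ≤ 1.
* Problem sizes in the test and acceptance runs (10⁵-step rotors, 100
  selection replicates, 10³–10⁴-frame bead ensembles) were chosen as the
  smallest sizes at which the statistical claims they check are
  well-resolved.

## Known limitations

Anisotropic-diffusion and model-free (Lipari–Szabo) parameterizations are
not provided; the timescale-grid fit subsumes their descriptive role here
but does not yield their interpretable order parameters. T2 predictions
omit exchange broadening. The SAXS module deliberately does not compute
solvent-corrected intensities. Trajectory parsing delegates to MDAnalysis;
formats it cannot read (or topologies without standard N/H/CA naming) must
enter via precomputed correlation functions.
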