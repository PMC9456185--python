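# Methods

## Phase solubility and the stability constant

A phase-solubility experiment dissolves excess guest in solutions of
increasing host concentration [H]ₜ and measures the total dissolved guest
[G]ₜ. For 1:1 complexation with stability constant Kc and intrinsic guest
solubility S₀, the diagram is exactly linear:

    [G]t = S0 + (Kc·S0 / (1 + Kc·S0)) · [H]t

so the slope lies in (0, 1) and Kc = slope/(S₀(1−slope)). `fit_diagram` is
an unweighted ordinary least-squares fit (no error model for the
concentrations is assumed); the A_L classification requires 0 < slope < 1
and r² ≥ 0.98 (configurable). A sub-threshold diagram is reported
"nonlinear" with a warning rather than an error — at realistic measurement
noise a genuinely linear diagram with a shallow slope can occasionally miss
the threshold, and the caller should see that rather than lose the fit.
A slope ≥ 1 makes the Higuchi–Connors denominator non-positive, so
`stability_constant` refuses it (domain error).

Concentrations are molar throughout; the CSV reader converts mM on request.
Absorbance data enter only through a user-supplied linear calibration —
no extinction coefficient is assumed.

## Van't Hoff analysis

`vant_hoff_fit` regresses ln Kc on 1/T by OLS:

    ln Kc = −ΔH/(R·T) + ΔS/R

with ΔH = −R·slope and ΔS = R·intercept, and ΔG(T) = ΔH − T·ΔS. The
intercept is ΔS/R — the standard Van't Hoff form; this is also the only
convention under which the fitted ΔG values equal −R·T·ln Kc_pred(T), an
identity the tests enforce. R defaults to 1.985×10⁻³ kcal mol⁻¹ K⁻¹ and the
reference temperature to 303 K, both configurable. Celsius temperatures are
converted with +273.15.

On the published stability constants the recomputed ΔG values at 303 K
(−3.24, −2.82, −2.42 kcal/mol for DMβCD, HPβCD, βCD) agree with the
published table at two decimals. ΔH and TΔS individually are more sensitive
to the rounding of the tabulated Kc values (integers M⁻¹): a ±0.5 M⁻¹
rounding perturbation moves ΔH by a few hundredths of a kcal/mol, which for
the smallest enthalpy (DMβCD, ~0.8 kcal/mol) is a few per cent. ΔG is
insensitive because the fitted line is evaluated inside the temperature
range. The end-to-end checks therefore pin ΔG at printed precision and allow
ΔH/TΔS a ±0.05 kcal/mol band.

## Trajectory descriptors

* **Superposition/RMSD** — Kabsch algorithm via SVD with the determinant
  correction, so the rotation is always proper even for mirror-related
  inputs. Selections of rank < 2 (coincident or collinear atoms) have no
  unique optimal rotation and raise a degeneracy error. RMSD is
  non-mass-weighted; the atom selection is the caller's (conventions for
  which atoms enter RMSD vary, so none is hard-wired).
* **Radius of gyration** — about the weighted centroid; mass-weighted when
  masses are supplied (standard atomic masses from the topology elements),
  unit weights otherwise.
* **Contacts** — inter-group atom pairs within a cutoff, 4.5 Å by default
  (a common heavy-atom contact convention; the count scales with the cutoff,
  so it is exposed as a parameter). "Native" contacts are those present in a
  reference frame, default frame 0 — i.e. the initial docked pose. Minimum
  image is applied for orthorhombic boxes only; boxless trajectories are
  treated as non-periodic.
* **Rim distances** — dO3-2(n) = |O3(n) − O2(n+1)| and
  dO4-4(n) = |O4(n) − O4(n+1)| with cyclic pairing (unit n_units pairs with
  unit 1), giving exactly n_units pairs per frame. The H-bond-possible
  fraction counts (frame, unit) pairs with dO3-2 ≤ 3.5 Å, a pure distance
  criterion (no angle or energy term).
* **Free-energy landscape** — F(x,y) = −k_BT ln P(x,y) on a uniform 2-D
  histogram (0.1 Å bins by default), with k_BT taken as molar R·T in
  kcal/mol (303 K default). F is shifted so the occupied-cell minimum is 0;
  empty cells are masked rather than assigned a ceiling value, so
  renormalizing exp(−F/k_BT) over occupied cells reproduces the empirical
  bin probabilities exactly — the invariant the tests assert to 1e-12.

## Solvation shells

The RDF normalizes shell counts by 4πr²·dr·ρ·n_frames·n_centers with
r the bin center and ρ the bulk solvent density (N/V from the box, or an
explicit override for non-periodic input). Water is represented by its
oxygen site. Defaults dr = 0.05 Å, r_max = 10 Å cover the first solvation
shell (~2.5 Å peak) with margin. First-minimum detection runs on a
moving-average-smoothed g(r) (window 3 bins) and scans for the first local
minimum after the first local maximum; profiles without that pattern return
"no minimum", which the hydration table renders as "-" — the behavior
expected for atoms buried in the host cavity. Coordination numbers integrate
4πρ g(r) r² by the trapezoid rule with the integrand anchored at r = 0.
SEM across replicates uses the n−1 standard deviation.

## MM/PBSA aggregation

Per-snapshot polar/non-polar solvation and molecular-mechanics components
are inputs; this package never computes electrostatics. The combination
terms are derived per snapshot, averaged within each replicate, and
summarized as cross-replicate mean ± SEM (n = 3 convention). The entropy
term TΔS enters once per replicate — normal-mode or quasi-harmonic entropies
are computed per replicate in standard practice, not per snapshot — with a
per-snapshot mode available. ΔG_bind is assembled from the mean terms, so
ΔE_MM = ΔE_vdW + ΔE_ele, ΔG_solv = polar + non-polar and
ΔG_bind = ΔE_MM + ΔG_solv − TΔS hold exactly (to 1e-12) on the summary;
derived terms are computed at full precision and rounded only for display,
so a rounded combination can differ from the sum of rounded components by
one unit in the last place. An alternative SEM across all pooled snapshots
is provided (`sem_mode="snapshot"`), since published tables do not always
state which convention they use; replicate-level is the default.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* each analysis assumes,
with defaults chosen to mirror the study conditions:

* diagrams over 0–10 mM host at four temperatures (20–50 °C), S₀ = 10⁻⁴ M
  (a poorly soluble guest), Gaussian measurement noise of 2×10⁻⁶ M (~1–2 %
  of the measured concentrations, a realistic UV-Vis calibration error);
* Kc(T) series exactly log-linear in 1/T;
* a geometric seven-unit ring (O4 circumradius 5 Å, the size of a
  β-cyclodextrin glycosidic ring) with the O3(n)–O2(n+1) separation
  constructed at exactly 3.0 Å, per-frame Gaussian jitter, optional guest
  atoms in the cavity and uniform single-site solvent in a periodic box;
* energy tables of independent Gaussians (100 snapshots × 3 replicates,
  per-snapshot SD 1 kcal/mol around the published component means).

All generators are deterministic per seed. The ring is geometric, not
chemical: no force field, no bonded terms, no correlations between frames.
Uniform solvent has g(r) = 1 and no solvation shell, so solvation tests
check the ideal-gas limit and normalization, not hydration structure.
Passing tests therefore validate the estimators and their numerics — OLS
recovery, superposition, histogram normalization, additivity — not the
physics of any real trajectory; published per-atom hydration numbers and
RMSD/Rg magnitudes require the study's actual simulations and are treated as
format references only.

Problem sizes in the analysis drivers (50–20 frames, 2000 waters, 200-seed
recovery studies) were chosen so the full pipeline runs in seconds while
keeping Monte-Carlo errors a few per cent — small enough to iterate on,
large enough that the statistical checks are meaningful.

## Known limitations

* Only the linear A_L regime is modeled; B_S/B_I/A_P profiles and 1:2
  stoichiometries are out of scope.
* Uncertainty propagation stops at regression r² and replicate SEM.
* Minimum-image support is orthorhombic-only; binary trajectory formats
  (DCD/XTC) are not read — multi-model PDB and XYZ + JSON sidecar are the
  supported interchange formats.
* H-bond detection is distance-only by design.
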