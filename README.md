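# archasym

Dental-formula statistics and bilateral shape-asymmetry analysis for the
pharyngeal arches of cyprinid fishes — or any paired bilateral structure
digitised with fixed landmarks and sliding semi-landmarks.

## The scientific problem

Clonal (gynogenetic) hybrid fish such as *Chrosomus eos-neogaeus* are
genetically identical within a lineage, so any phenotypic variation among
them must come from the environment or from developmental noise.  Two
phenotypes of their tooth-bearing fifth branchial arch make this system a
natural laboratory:

* the **dental formula** — a discrete count notation `a,b–c,d` giving the
  teeth on the minor and major rows of the left and right hemi-arches
  (e.g. `1,5–5,1` is symmetric, `1,5–4,1` lacks one right major-row
  tooth);
* the **3D shape** of the arch, captured by 7 fixed landmarks and 26
  sliding semi-landmarks per side (33 points × 3 coordinates), digitised
  twice per side to quantify measurement error.

`archasym` implements the complete analysis chain for such data:

1. **Dental statistics** — formula parsing and symmetry classification,
   Simpson's diversity *D* = 1 − Σᵢ pᵢ² of formula counts, grouped
   frequency tables, and 2×2 Pearson χ² contingency tests.
2. **Superimposition** — Generalised Procrustes Analysis (translation,
   unit-centroid-size scaling, proper rotations only), thin-plate-spline
   bending energy, semi-landmark sliding by the minimum bending-energy
   criterion, and projection to the shape tangent space.
3. **Matching symmetry** — the right side is reflected (x → −x) and both
   sides jointly superimposed; a Procrustes ANOVA then decomposes shape
   variation into *Individual*, *Side* (directional asymmetry, DA,
   tested over the individual × side interaction), *Individual × Side*
   (fluctuating asymmetry, FA, tested over digitising error) and
   *Measurement error*.  P-values come from residual randomisation
   (RRPP) permutation.  Per-landmark left–right tests control for
   sampling site and report Ezekiel-adjusted R² with sign-flip
   permutation P (raw and Benjamini–Hochberg adjusted).
4. **Multivariate ecology-style statistics** — redundancy analysis (RDA)
   and partial RDA with adjusted R², two-factor variance partitioning,
   trajectory (magnitude/angle) comparison of group shape differences,
   and PCA scores.
5. **Synthetic data** — a generator of bilateral 33-point crescent
   configurations with controllable individual, directional, fluctuating
   and measurement variance components, site effects and site-dependent
   formula frequencies, so the whole pipeline is testable end to end.

## Worked example

Run the full pipeline on the built-in synthetic study-design dataset
(66 clonal individuals from 7 sites, 2 sides × 2 digitising sessions,
directional asymmetry coupled to the alternative dental formula):

```bash
cat > config.yaml <<EOF
input_table: null          # null -> generate the synthetic dataset
out_dir: demo_out
seed: 1
n_perm: 999
EOF
archasym run --config config.yaml
```

The matching-symmetry section of the summary reads (seed 1):

```
  group            effect  df     SS     MS       F     P
1,5–4,1              Side   1 0.0294 0.0294  9.2045 0.001
1,5–4,1 Individual × Side  30 0.0957 0.0032  8.6098 0.001
1,5–5,1              Side   1 0.0024 0.0024  0.7543 0.875
1,5–5,1 Individual × Side  34 0.1060 0.0031  8.5856 0.001
```

Directional asymmetry is detected only in the group carrying the
asymmetric `1,5–4,1` formula (Side P = 0.001 vs 0.875), while fluctuating
asymmetry — simulated in every individual — is significant in both
groups, exactly the structure the generator injected.  The
measurement-error ANOVA attributes 98.4 % (L) / 98.2 % (R) of shape
variation to individuals rather than digitising sessions, and the
partial RDA reports a pure site effect of R²_adj = 0.165 (L side,
P = 0.001) after controlling for dental formula.

Other useful subcommands: `simulate`, `diversity`, `gpa`, `asymmetry`,
`rda`, `trajectory`, `report` (see `archasym --help`).

As a library:

```python
from archasym import simpson_diversity, chisq_2x2

simpson_diversity({"0,5–5,0": 67, "0,5–4,0": 10})   # 0.2260
chisq_2x2([[10, 67], [11, 126]])                     # chi2=1.3691, P=0.242
```

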