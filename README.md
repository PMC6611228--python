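# sirtlq

Radiobiological modelling of protracted Y-90 β⁻ irradiation versus
external-beam radiotherapy (EBRT), for radiation biologists and medical
physicists working on Y-90 selective internal radiation therapy (SIRT) of
liver tumours.

In SIRT the dose is delivered continuously over days by a decaying source
rather than in minutes, so sublethal damage is repaired during delivery and
the quadratic term of the linear-quadratic (LQ) survival model is strongly
suppressed. `sirtlq` packages the full analysis chain needed to quantify
this:

1. **Dosimetry** — cumulated dose to a cell monolayer from a decaying Y-90
   source whose S-value (dose rate per unit activity, MIRD formalism) drifts
   linearly from `S_initial` to `S_final` as the culture medium evaporates:

   ```
   D(T) = (A0/λ) [ (S_f − S_i)/(λT) · (1 − (1+λT)e^{−λT}) + S_i (1 − e^{−λT}) ]
   ```

   with λ = ln2 / 64.1 h for Y-90, validated against adaptive quadrature of
   the defining integral.

2. **Survival fitting** — clonogenic colony counts → surviving fractions
   (normalised to the 0 Gy controls of each biological repeat), then a
   restricted-maximum-likelihood mixed model

   ```
   −ln(SF) = αD + βD² + b_i + ε,   b_i ~ N(0, σ_b²) per replicate set,
   ```

   with delta-method standard errors for α/β and Wald tests for α, β.

3. **Protraction and equivalence** — the Lea–Catcheside factor G for a
   mono-exponentially decaying source (finite exposure and the fully decayed
   limit G∞ = T_rep/(T_rep + T_phys)), inversion of G for the repair
   half-time T_rep, RBE_max = α_Y90/α_EBRT, and the biologically effective
   dose machinery

   ```
   BED_EBRT = nd (1 + d/(α/β))
   BED_Y90  = D (RBE_max + G∞ D/(α/β))
   EQDd     = BED_Y90 / (1 + d/(α/β))
   ```

   that converts a Y-90 absorbed dose into the equivalent EBRT dose in
   d-Gy fractions.

4. **Synthetic assays** — a Poisson colony-count generator with
   replicate-level random intercepts that matches the fitted model exactly,
   so the whole pipeline is testable end to end (parameter recovery,
   CI coverage) without any laboratory data.

## Worked example

Infer the repair half-time of DLD-1 cells from the ratio of the quadratic
coefficients fitted under a 6-day Y-90 exposure (β = 0.00109 Gy⁻²) and under
acute 6 MV x-rays (β = 0.0189 Gy⁻²):

```sh
$ sirtlq protraction --beta-rnt 0.00109 --beta-ebrt 0.0189
{
  "G_T": 0.05767195767195767,
  "G_inf": 0.03773881207790231,
  "T_rep_h": 2.5139306090243965,
  ...
}
```

The β ratio 0.0577 is read as the Lea–Catcheside factor of the 144 h
exposure; inverting it gives a sublethal-damage repair half-time of 2.51 h,
and a fully decayed Y-90 source would retain only G∞ ≈ 3.8% of the acute
quadratic kill. Plugging G∞, RBE_max = 0.388 and (α/β) = 14.4 Gy into the
equivalence formula shows that a 60 Gy Y-90 absorbed dose matches only
≈ 28.7 Gy of EBRT in 2 Gy fractions for this cell line.

Dose table for a 20 MBq Y-90 DOTATATE source irradiating a dish stack for
6 days (doses in Gy at each dish position):

```sh
$ printf 'activity_MBq: 20\nformulation: DOTATATE\nduration_h: 144\n' > exposure.yaml
$ sirtlq dose exposure.yaml
position,S_initial,S_final,dose_Gy
+2,8.4,10.08,5.492588950551687
+1,47.3,56.76,30.92850682870176
-1,24.3,29.16,15.889275178381665
-2,2.06,2.472,1.3469920521591043
```

The ladder of (activity × position) doses, 0.7–31 Gy, is exactly the design
the synthetic Y-90 experiment (`sirtlq simulate --protracted`) reproduces.

Other subcommands: `simulate` / `fit` / `recover` (synthetic assay →
mixed-model fit → recovery report), `eqd` (equivalence curves), and
`paper-mode` (below). The same functionality is importable from
`sirtlq` as a library.

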