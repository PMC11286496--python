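# viscoclass

Machine-learning diagnosis of liver tissue state from viscoelastic creep
markers.

Liver fibrosis stiffens tissue, and stiffness (elastic modulus) is already
used as a mechanical biomarker.  But soft tissue is viscoelastic: under a
step force from an AFM spherical probe it creeps with a two-stage power law,
fast (exponent αL ∈ (0.5, 1)) at short times and slow (αR ≈ 0.2) at long
times.  Characterizing the creep response with a hierarchical viscoelastic
model yields a nine-dimensional marker vector per measurement —
E1, E2, E3, Esum, η, τ, fT, αL, αR — and a soft-margin SVM with a Gaussian
kernel, κ(xᵢ, xⱼ) = exp(−‖xᵢ − xⱼ‖²/2σ²), trained on those markers can
classify healthy, drug-treated and fibrotic tissue, rank the markers by
importance, and quantify drug efficacy as the gap between
treated-vs-diseased and treated-vs-healthy classification accuracies.

Because no raw AFM dataset for this design is public, the package ships a
first-class synthetic cohort generator calibrated to the reported group
statistics (mean total modulus 456.1 / 681.4 / 2280.5 in healthy / treated /
diseased, 800 measurements per group, 3% multiplicative measurement noise).
It is intended for methodologists who want a tested, reproducible
implementation of the whole pipeline: forward rheology → simulated
measurement → marker extraction → classification → marker selection → drug
assessment.

## The model in brief

Relaxation modulus (Laplace domain, reference rate ω0 = 1 rad/s):

    Ĝ(s) = E3 + E2 (s/ω0)^αR + E1 (s/ω0)^αL + η s

Creep compliance J(t) is the Gaver–Stehfest inverse of 1/(s Ĝ(s));
indentation records map to compliance through Hertz contact,
J = 4√R δ^{3/2} / (3F(1−ν²)).  Derived markers: Esum = E1+E2+E3,
τ = η/E1, and the transition frequency fT = (ω0/2π)(E2/E1)^{1/(αL−αR)}
where the fast and slow branches cross.  Marker recovery from noisy records
is a penalized least-squares fit whose design (and identifiability limits)
are documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from viscoclass import (
    CohortConfig, default_group_specs, generate_cohort, extract_features,
    split_train_test, cross_validate, train_classifier, evaluate,
)

specs = tuple(s.__class__(**{**s.__dict__, "n": 200}) for s in default_group_specs())
cohort = generate_cohort(CohortConfig(group_specs=specs, seed=1))
table, report = extract_features(cohort, seed=1)
print(f"fits kept: {report.n_kept}/{report.n_total}, median R^2 = {report.median_r2:.3f}")

hd = table[table["status"].isin([0, 2])]          # healthy vs diseased
train, test = split_train_test(hd, seed=1)        # stratified 70/30
C, sigma, cv_acc, _ = cross_validate(train, ["Esum"], k=10)
clf = train_classifier(train, ["Esum"], C=C, sigma=sigma)
m = evaluate(clf, test)
print(f"healthy vs diseased, Esum only: C={C}, sigma={sigma}, "
      f"CV acc={cv_acc:.3f}, test acc={m.accuracy:.3f}, AUC={m.auc:.3f}")
```

Output:

    fits kept: 600/600, median R^2 = 0.993
    healthy vs diseased, Esum only: C=1.0, sigma=0.5, CV acc=0.989, test acc=0.983, AUC=1.000

Every fit explains its noisy creep record (median R² 0.993 against the 0.9
retention threshold), and the total modulus alone separates healthy from
diseased tissue almost perfectly — the fibrotic group is five-fold stiffer,
far beyond the within-group spread.  Distinguishing *treated* from healthy
tissue is much harder (their moduli overlap) and is where the exponent and
transition-frequency markers contribute.

There is also a CLI for running stages from a shell:

    viscoclass simulate --seed 1 --out cohort/
    viscoclass extract cohort/ --out features/
    viscoclass assess features/feature_table.csv --out verdict/
    viscoclass run-all --config cfg.yaml --seed 1 --out results/

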