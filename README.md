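# affilex

Affiliation-exposure networks and two-mode network autocorrelation models
for studying peer influence on user engagement in digital health
communities.

## The problem

In peer-support forums for chronic conditions such as type 2 diabetes,
users influence each other not only through direct replies but through
*shared ways of communicating*: two users who both ask questions, or both
push assertions, within the same conversation theme occupy the same
communicative niche. `affilex` operationalizes this as a **two-mode
affiliation network** per communication theme: users form one node set,
speech-act categories (assertion, statement, directive, question, emotion,
stance, declarative, expressive) the other, and a user is affiliated with a
speech act when they express it at least as often as the network's median
positive count. Speech acts split into two communication styles:
**push-in** (assertion, stance, declarative, directive, statement) and
**interactive turn-taking** (question, expressive, emotion).

The package targets computational social scientists and health-informatics
researchers who want to quantify whether exposure to peers through shared
communication context is associated with engagement (posting frequency),
and by how much.

## The model

From the binarized user-by-speech-act matrix *A* (n × k), the
coaffiliation matrix is *C = A Aᵀ*: off-diagonal *C_ij* counts the speech
acts users *i* and *j* coexpress; the diagonal *D_i = C_ii* counts user
*i*'s affiliated acts. **Affiliation exposure** is the coaffiliation-
weighted mean of peers' engagement, diagonal excluded:

    F_i = Σ_{j≠i} C_ij y_j / Σ_{j≠i} C_ij

Dependence of engagement on exposure is estimated with the two-mode
**linear network autocorrelation model**

    y = ρ W y + X β + γ D + ε,   ε ~ N(0, σ² I)

where *W* is the row-normalized, zero-diagonal form of *C* (so that *W y*
equals *F* entrywise), *X* holds an intercept and binary persona covariates
(medication use, pre-existing diagnosis, lifestyle changes) extracted from
users' forum signatures by lexicon rules, and *D* controls for each user's
affiliation degree. Estimation is profile maximum likelihood: β, γ, σ² have
closed forms given ρ; the one-dimensional profile is maximized over the
spectral interval (1/λ_min, 1/λ_max) of *W*, with log|det(I − ρW)| computed
from the precomputed eigenvalues. Standard errors come from the numerically
differentiated observed information.

Because real forum corpora of this kind cannot be redistributed, the
package ships a synthetic community generator (`affilex.synth`) whose
marginals — posting rates, yearly activity, multi-label theme/speech-act
structure, persona distribution — are anchored to the published
descriptive statistics of the American Diabetes Association T2D community
(529 signature users, ~57k messages, 2014–2021), plus a recovery mode that
simulates engagement directly from the model at known (ρ, β, γ, σ).

## Worked example

```python
import numpy as np
from affilex import (GeneratorConfig, affiliation_exposure, fit_nam,
                     generate_recovery_instance)

# affiliation exposure on a 3-user coaffiliation matrix
C = np.array([[1, 0, 1],
              [0, 1, 1],
              [1, 1, 2]])
y = np.array([10.0, 20.0, 30.0])
print(affiliation_exposure(C, y).to_numpy())

# fit the model on a simulated instance with known rho = 0.3
inst = generate_recovery_instance(GeneratorConfig(seed=1, n_users=300), rho=0.3)
fit = fit_nam(inst.y, inst.weight, inst.X.to_numpy(), inst.D,
              names=list(inst.X.columns))
print(f"rho = {fit.rho:.3f} (SE {fit.rho_se:.3f}, p = {fit.rho_p:.2g})")
print(fit.coef.round(3))
```

prints

```
[30. 30. 15.]
rho = 0.308 (SE 0.025, p = 5.7e-36)
                estimate     se    p
intercept          4.717  0.256  0.0
medication        -0.571  0.128  0.0
diagnosis          0.701  0.154  0.0
lifestyle          0.604  0.133  0.0
sas_affiliated     0.682  0.060  0.0
```

Users 1 and 2 each coaffiliate only with user 3, so their exposure is 30;
user 3 coaffiliates equally with both, so 15. The fit recovers the
generating autocorrelation ρ = 0.3 within one standard error, and the
persona and degree coefficients recover their generating values
(−0.5, 0.5, 0.5 and 0.7).

## The analysis pipeline

Numbered drivers under `analysis/` reproduce the full study flow on the
synthetic community and write their outputs under `results/`:

1. `01_simulate_community.py` — generate the 529-user ada-like corpus;
2. `02_extract_personas.py` — rule-based persona extraction + audit;
3. `03_descriptive_tables.py` — yearly / persona / per-theme summaries;
4. `04_build_networks.py` — 12 theme × style networks, exposure, GEXF;
5. `05_fit_models.py` — 12 model fits and the regression table;
6. `06_recovery_experiments.py` — estimator bias/coverage and the
   communication-style sign pattern against known ground truth.

The same stages are available as a CLI (`affilex simulate | persona |
network | fit | report`).

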