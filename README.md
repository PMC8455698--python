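# jcouple

Predicting NMR scalar coupling constants from 3-D molecular structure
with an angle-attention graph neural network.

## What this is

The scalar coupling constant (SCC, in Hz) between two nuclei — written
<sup>N</sup>J<sub>AB</sub>, where N is the number of bonds on the path
between atoms A and B — is a central NMR observable for elucidating
molecular structure.  Measuring SCCs experimentally is expensive and
computing them with DFT is slow, so data-driven prediction from
geometry alone is attractive for screening.  `jcouple` implements a
graph neural network for this task whose design bakes in the key piece
of spectroscopic prior knowledge, the **Karplus equation**

> J = A·cos²φ + B·cosφ + C,

which ties a vicinal (3-bond) coupling to the torsion φ of its bond
path.  The model handles the eight H-containing coupling types
(¹J<sub>HC</sub>, ¹J<sub>HN</sub>, ²J<sub>HC</sub>, ²J<sub>HN</sub>,
²J<sub>HH</sub>, ³J<sub>HC</sub>, ³J<sub>HN</sub>, ³J<sub>HH</sub>)
over C/H/N/O/F molecules, reads the public scalar-coupling competition
CSV dialect, and ships a synthetic generator that produces desk-scale
molecules with Karplus-law labels so the whole pipeline is testable
offline.

The network (see `docs/methods.md` for the full account):

1. **bond message passing** over chemical bonds, each directed bond
   weighted by a Karplus-form *bond-angle attention*
   attn = Σᵢ (A′cos²θᵢ + B′cosθᵢ + C′)/M over its M neighbouring bond
   angles, with three global learnable coefficients initialised at
   (0.12, 0.99, 0.27);
2. **coupling message passing** over the labelled atom pairs (no
   attention factor);
3. **multi-head self-attention** softmax(QKᵀ/√d_model)V over each
   molecule's coupled atoms;
4. an **MLP decoder** on f_atom0 ⊕ f_atom1 ⊕ f_mol.

Evaluation uses the grouped log(MAE): the mean over coupling types of
ln(MAE), which weights the ~100 Hz one-bond couplings and the ~Hz
three-bond couplings equally.  The whole model, including training,
runs on a small gradient-checked numpy autodiff core — no GPU or deep
learning framework required.

## Worked example

Train a small model on synthetic torsion-driven data: 300 molecules,
one noise-free ³J<sub>HH</sub> coupling each, labels from
J = 7cos²φ − cosφ + 5 on the true dihedral φ.  Runs in well under a
minute on one CPU core.

```python
import numpy as np
from jcouple import (SyntheticConfig, generate_dataset,
                     ScalarCouplingRegressor)
from jcouple.io import Dataset
from jcouple.model import constant_mean_baseline
from jcouple.synthetic import split_dataset

ds, _ = generate_dataset(
    SyntheticConfig(n_molecules=300, noise_sd=0.0, types=("3JHH",), seed=0))
rng = np.random.default_rng(0)                       # one pair per molecule
by_mol = {}
for r in ds.records:
    by_mol.setdefault(r.molecule, []).append(r)
ds = Dataset(molecules=ds.molecules,
             records=[v[rng.integers(len(v))] for v in by_mol.values()])
train, test = split_dataset(ds, train_frac=0.8, seed=0)

est = ScalarCouplingRegressor(d_model=64, n_heads=4, hidden_sizes=(128, 64),
                              epochs=40, batch_size=16, max_lr=1e-2,
                              dtype="float32", random_state=0).fit(train)
report = est.evaluate(test)

y = np.array([r.scc for r in test.records])
base = np.abs(constant_mean_baseline(train, test) - y).mean()
mae = report.per_type_mae["3JHH"]
print(f"{len(train.records)} training / {len(test.records)} held-out couplings")
print(f"validation MAE      = {mae:.2f} Hz")
print(f"label SD            = {y.std():.2f} Hz   (MAE/SD = {mae/y.std():.2f})")
print(f"constant-mean MAE   = {base:.2f} Hz   (MAE/baseline = {mae/base:.2f})")
print(f"grouped log(MAE)    = {report.score:.2f}")
print("fitted (A', B', C') =", tuple(round(c, 3) for c in est.attention_coeffs_))
```

Output of this exact script:

```
218 training / 54 held-out couplings
validation MAE      = 0.09 Hz
label SD            = 2.35 Hz   (MAE/SD = 0.04)
constant-mean MAE   = 2.02 Hz   (MAE/baseline = 0.05)
grouped log(MAE)    = -2.40
fitted (A', B', C') = (0.129, 0.986, 0.268)
```

The model recovers the Karplus relation almost exactly: 0.09 Hz mean
error against a 2.35 Hz label spread, twenty times better than the
constant-mean baseline.  The fitted attention coefficients stay near
their published initial values.  Two caveats worth knowing before
extrapolating: on *densely* labelled data (every H-pair of every
molecule), exchange-symmetric hydrogens make some pairs provably
indistinguishable to this decoder, which caps dense-data accuracy; and
synthetic labels are far simpler than DFT ones.  Both are quantified
in `docs/methods.md`.

The same workflow is available from the shell:

```bash
jcouple simulate --n-molecules 100 --seed 0 --out data/
jcouple train    --structures data/structures.csv --couplings data/train.csv \
                 --epochs 40 --out run/
jcouple predict  --checkpoint run/checkpoint.npz \
                 --structures data/structures.csv --couplings data/test.csv \
                 --out submission.csv
jcouple evaluate --checkpoint run/checkpoint.npz \
                 --structures data/structures.csv --couplings data/train.csv
jcouple ablate   --structures data/structures.csv --couplings data/train.csv \
                 --out ablation/
jcouple analyze  --structures data/structures.csv --couplings data/train.csv \
                 --decoy-seed 1 --out analysis/
```

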