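"""Interpretability analyses: ablation, rank correlations, PCA embedding.

The ablation protocol retrains the model under four arms that differ only
in the two angle toggles (bond-angle attention; angle features), with
identical data and seeds, and compares final validation scores.  The
rank-correlation analysis asks which geometric feature co-varies most
with the coupling constant; the PCA embedding projects the model's
per-record representations to 2-D for qualitative inspection of how the
coupling types separate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .features import FeatureConfig, featurize
from .io import Dataset
from .model import ScalarCouplingRegressor
from .synthetic import split_dataset

#: The four ablation arms: (use_angle_attention, use_angle_features).
ABLATION_ARMS: dict[str, tuple[bool, bool]] = {
    "base": (False, False),
    "attention_only": (True, False),
    "angle_features_only": (False, True),
    "full": (True, True),
}


@dataclass
class AblationReport:
    """Validation-score curves and final scores of the four ablation arms."""

    arms: dict[str, dict] = field(default_factory=dict)
    seeds: tuple[int, ...] = ()

    def final_score(self, arm: str) -> float:
        """Median (over seeds) of the arm's final validation score."""
        return float(np.median(self.arms[arm]["final_scores"]))

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = json.dumps({"arms": self.arms, "seeds": list(self.seeds)}, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @staticmethod
    def from_json(source: str | Path) -> "AblationReport":
        try:
            is_file = Path(str(source)).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        d = json.loads(text)
        return AblationReport(arms=d["arms"], seeds=tuple(d["seeds"]))


def ablate(
    dataset: Dataset,
    seeds: Sequence[int] = (0, 1, 2),
    **estimator_params,
) -> AblationReport:
    """Run the four-arm ablation with shared data and seeds.

    ``estimator_params`` configure the shared model/training setup; the
    arms override only the two angle toggles.  Each arm is trained once
    per seed; per-epoch validation curves and final scores are recorded.
    """
    report = AblationReport(seeds=tuple(int(s) for s in seeds))
    for arm, (use_attn, use_feats) in ABLATION_ARMS.items():
        curves, finals = [], []
        for seed in seeds:
            est = ScalarCouplingRegressor(
                use_angle_attention=use_attn,
                use_angle_features=use_feats,
                random_state=int(seed),
                **estimator_params,
            )
            est.fit(dataset)
            curve = est.history_["val_score"].tolist()
            curves.append(curve)
            finals.append(float(est.history_["val_score"].iloc[-1]))
        report.arms[arm] = {
            "use_angle_attention": use_attn,
            "use_angle_features": use_feats,
            "val_curves": curves,
            "final_scores": finals,
        }
    return report


def coupling_feature_table(
    dataset: Dataset, extra_decoy: Optional[int] = None
) -> pd.DataFrame:
    """Per-record geometric feature table for correlation analysis.

    Columns: coupled-atom distance, 1/d, cos(dihedral), cos(bond angle),
    cos(angle0), cos(angle1) (absent values as NaN), the coupling type
    and the SCC.  ``extra_decoy`` (a seed) adds an independent random
    column ``decoy`` — a feature with no relation to the labels, used as
    a negative control for correlation magnitudes.
    """
    config = FeatureConfig(normalize=False)
    mols = featurize(dataset, config)
    rows = []
    for m in mols:
        for k, pos in enumerate(m.rec_pos):
            rec = dataset.records[pos]
            x = m.cpl_x[2 * k]  # both directed copies carry the same features
            rows.append(
                {
                    "record": int(pos),
                    "type": rec.ctype,
                    "distance": x[8],
                    "inv_distance": x[9],
                    "cos_dihedral": x[11] if x[12] else np.nan,
                    "cos_bond_angle": x[13] if x[14] else np.nan,
                    "cos_angle0": x[15] if x[16] else np.nan,
                    "cos_angle1": x[17] if x[18] else np.nan,
                    "scc": rec.scc,
                }
            )
    df = pd.DataFrame(rows).sort_values("record").reset_index(drop=True)
    if extra_decoy is not None:
        rng = np.random.default_rng(extra_decoy)
        df["decoy"] = rng.normal(size=len(df))
    return df


def spearman_matrix(table: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Spearman rank-correlation matrix (average ranks for ties).

    Pairwise complete observations; constant columns yield NaN against
    everything (the rank correlation is undefined there), with unit
    diagonal kept.
    """
    if columns is None:
        columns = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    k = len(columns)
    out = np.full((k, k), np.nan)
    for i in range(k):
        out[i, i] = 1.0
        for j in range(i + 1, k):
            a = table[columns[i]].to_numpy(dtype=float)
            b = table[columns[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 2 or np.all(a[ok] == a[ok][0]) or np.all(b[ok] == b[ok][0]):
                continue
            rho = stats.spearmanr(a[ok], b[ok]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=list(columns), columns=list(columns))


def pca_embed(X: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centred projection onto the top-k principal axes.

    Returns (coordinates (n, k), explained-variance ratios).  Requires at
    least 2 samples.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("pca_embed needs at least 2 samples")
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_
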