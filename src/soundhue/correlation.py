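"""Feature–colour correlation screening with familywise control.

Every audio feature and colour-patch parameter is Box-Cox power
transformed (per variable, shifted positive where needed, λ by
profile-likelihood) so that Pearson correlation is defensible; each
feature × parameter cell is then tested at the Dunn-Šidák per-test
level α_c = 1 − (1 − α_fw)^(1/m) and tiered as familywise-significant,
nominally significant (α_c < p ≤ 0.05), or neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TransformResult", "box_cox", "dunn_sidak_alpha", "correlation_table"]


@dataclass(frozen=True)
class TransformResult:
    variable: str
    lmbda: float
    shift: float
    shapiro_p: float


def box_cox(values, name: str = "") -> tuple[TransformResult, np.ndarray]:
    """Shifted Box-Cox transform with profile-likelihood λ.

    Values are shifted by max(0, ε − min) with ε = 1e−6 · range so the
    transform sees strictly positive input; strictly positive data are
    left unshifted.  Returns the transform metadata (λ, shift,
    post-transform Shapiro p) and the transformed values.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("Box-Cox needs at least 5 values")
    rng_ = np.ptp(x)
    if rng_ == 0:
        raise ValueError(f"constant variable {name!r}; Box-Cox undefined")
    eps = 1e-6 * rng_
    shift = max(0.0, eps - x.min())
    z, lmbda = stats.boxcox(x + shift)
    shapiro_p = float(stats.shapiro(z).pvalue)
    return TransformResult(name, float(lmbda), float(shift), shapiro_p), z


def dunn_sidak_alpha(alpha_fw: float, m: int) -> float:
    """Per-comparison level controlling familywise error over m tests."""
    if not 0.0 < alpha_fw < 1.0:
        raise ValueError("alpha_fw must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha_fw) ** (1.0 / m)


def correlation_table(features: pd.DataFrame, patches: pd.DataFrame,
                      alpha_fw: float = 0.05, m: int | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r of every Box-Cox-transformed feature × parameter pair.

    ``features`` (n × p features) and ``patches`` (n × 4, columns size,
    L, a, b) must be row-aligned.  ``m`` is the Dunn-Šidák correction
    divisor; default is the number of computed cells.

    Returns ``(cells, transforms)``: the long cell table (feature,
    parameter, r, p, tier) and the per-variable transform table.
    """
    if len(features) != len(patches):
        raise ValueError("features and patches must have the same n")
    if len(features) < 5:
        raise ValueError("need n >= 5")
    m = m if m is not None else features.shape[1] * patches.shape[1]
    alpha_c = dunn_sidak_alpha(alpha_fw, m)

    transforms, zcols = [], {}
    for name, col in list(features.items()) + list(patches.items()):
        tr, z = box_cox(col.to_numpy(), name=str(name))
        transforms.append(tr)
        zcols[str(name)] = z

    rows = []
    for f in features.columns:
        for p in patches.columns:
            r, pv = stats.pearsonr(zcols[str(f)], zcols[str(p)])
            tier = ("pass-familywise" if pv <= alpha_c
                    else "nominal" if pv <= 0.05 else "none")
            rows.append({"feature": f, "parameter": p,
                         "r": float(r), "p": float(pv), "tier": tier})
    cells = pd.DataFrame(rows)
    tdf = pd.DataFrame([t.__dict__ for t in transforms])
    return cells, tdf
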