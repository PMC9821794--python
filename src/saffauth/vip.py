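"""Variable importance in projection (VIP).

VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ), where
SSY_a = (t_a' t_a) * sum_m q_am^2 is the Y-variance captured by component a.
The squared scores average exactly 1 over the p variables, so 1 is the
natural cut-off for calling a variable significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import PLSModel

__all__ = ["VIPResult", "vip_scores"]

VIP_CUTOFF = 1.0


@dataclass(frozen=True)
class VIPResult:
    vip: np.ndarray  # p scores, all >= 0
    mask: np.ndarray  # p booleans, score >= 1

    def as_frame(self, axis: np.ndarray) -> pd.DataFrame:
        """Tabulate scores against wavenumbers, most important first."""
        df = pd.DataFrame(
            {"wavenumber": np.asarray(axis), "vip": self.vip, "significant": self.mask}
        )
        return df.sort_values("vip", ascending=False, ignore_index=True)


def vip_scores(model: PLSModel) -> VIPResult:
    if not isinstance(model, PLSModel) or model.n_components < 1:
        raise ValueError("vip_scores requires a fitted PLS model")
    W, Q, T = model.W, model.Q, model.T
    p = W.shape[0]
    tt = np.einsum("na,na->a", T, T)  # per-component t'a t_a
    ssy = tt * np.einsum("ma,ma->a", Q, Q)
    wnorm2 = np.einsum("pa,pa->a", W, W)
    vip = np.sqrt(p * (W**2 / wnorm2) @ ssy / ssy.sum())
    return VIPResult(vip=vip, mask=vip >= VIP_CUTOFF)
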