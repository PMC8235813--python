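"""Model selection over K via the second-order rate of change of lnP."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._errors import ValidationError


@dataclass
class EvannoTable:
    ks: list[int]
    mean_lnP: dict[int, float]
    sd_lnP: dict[int, float]
    l_prime: dict[int, float] = field(default_factory=dict)
    l_double_prime: dict[int, float] = field(default_factory=dict)
    delta_k: dict[int, float] = field(default_factory=dict)

    @property
    def best_k(self) -> int | None:
        """argmax of delta-K over interior K; None when inconclusive."""
        defined = {k: v for k, v in self.delta_k.items() if np.isfinite(v)}
        if not defined or all(v == 0 for v in defined.values()):
            return None
        return max(defined, key=lambda k: (defined[k], -k))

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.ks:
            rows.append({
                "K": k,
                "mean_lnP": self.mean_lnP[k],
                "sd_lnP": self.sd_lnP[k],
                "l_prime": self.l_prime.get(k, np.nan),
                "l_double_prime": self.l_double_prime.get(k, np.nan),
                "delta_k": self.delta_k.get(k, np.nan),
            })
        return pd.DataFrame(rows)


def evanno(lnP_by_K: dict[int, list[float]]) -> EvannoTable:
    """Build the delta-K table from per-run lnP values grouped by K.

    Requires at least 3 consecutive K values with >= 2 runs each.  L'(K) is
    the first difference of mean lnP, L''(K) its absolute second difference,
    and delta-K = L''(K) / sd(lnP at K), defined only for interior K with a
    positive standard deviation.
    """
    ks = sorted(lnP_by_K)
    if len(ks) < 3:
        raise ValidationError("the Evanno method needs at least 3 K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValidationError(f"K values must be consecutive, got {ks}")
    for k in ks:
        if len(lnP_by_K[k]) < 2:
            raise ValidationError(f"K={k}: at least 2 runs are required")
    mean = {k: float(np.mean(lnP_by_K[k])) for k in ks}
    sd = {k: float(np.std(lnP_by_K[k], ddof=1)) for k in ks}
    table = EvannoTable(ks=ks, mean_lnP=mean, sd_lnP=sd)
    for k in ks[1:]:
        table.l_prime[k] = mean[k] - mean[k - 1]
    for k in ks[1:-1]:
        table.l_double_prime[k] = abs(table.l_prime[k + 1] - table.l_prime[k])
        if sd[k] > 0:
            table.delta_k[k] = table.l_double_prime[k] / sd[k]
        else:
            table.delta_k[k] = float("nan")  # undefined, excluded from argmax
    return table
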