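"""Small-sample Akaike model comparison for the fitted hypotheses.

With the weighted sum-of-squares cost standing in for -2 log-likelihood,
the small-sample-corrected criterion is

    AICc = 2k + V_min + (2k^2 + 2k) / (m - k - 1),

where ``k`` is the number of optimized parameters and ``m`` the number of
fitted residual terms.  For the standard design -- 4 conditions, 5
timepoints with the first serving as initial condition -- ``m`` is
4 x 4 = 16; it is overridable because this count is a modeling choice.
Smaller AICc means a more preferable model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Dict, List, Sequence

import pandas as pd

from .pim_models import count_free_params

if TYPE_CHECKING:  # pragma: no cover
    from .core_data import ExpressionDataset, FitResult

__all__ = ["aicc", "default_m", "ComparisonReport", "compare_models"]


def aicc(v_min: float, k: int, m: int) -> float:
    """Corrected Akaike criterion for a fit with cost ``v_min``.

    Raises ``ValueError`` when ``m <= k + 1`` (the correction is undefined).
    """
    if v_min < 0:
        raise ValueError("v_min must be nonnegative")
    if k < 1:
        raise ValueError("k must be a positive integer")
    if m <= k + 1:
        raise ValueError(
            f"small-sample correction undefined for m={m}, k={k} (need m > k + 1)"
        )
    return 2.0 * k + v_min + (2.0 * k * k + 2.0 * k) / (m - k - 1.0)


def default_m(dataset: "ExpressionDataset") -> int:
    """Residual count: conditions x (timepoints - 1).

    The first timepoint is consumed as the initial condition, so it carries
    no residual.
    """
    return len(dataset.conditions) * (len(dataset.timepoints) - 1)


@dataclass
class ComparisonReport:
    """Ranking of hypothesis fits by AICc (ascending)."""

    entries: List[Dict[str, float]]  # hypothesis, k, v_min, aicc, delta_aicc
    ranking: List[str]
    selected: str
    m: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries).set_index("hypothesis").loc[self.ranking]

    def __str__(self) -> str:
        lines = [f"model ranking (m = {self.m}; lower AICc preferred):"]
        for rank, hyp in enumerate(self.ranking, start=1):
            e = next(x for x in self.entries if x["hypothesis"] == hyp)
            lines.append(
                f"  {rank}. {hyp}: k={e['k']}, V_min={e['v_min']:.4g}, "
                f"AICc={e['aicc']:.4g} (dAICc={e['delta_aicc']:.4g})"
            )
        return "\n".join(lines)


def compare_models(
    fits: Sequence["FitResult"],
    dataset: "ExpressionDataset | None" = None,
    m: int | None = None,
) -> ComparisonReport:
    """Rank fits of the same dataset by recomputed AICc.

    All fits must carry the same dataset fingerprint; AICc is recomputed
    here from ``v_min`` and the schema parameter count rather than trusted
    from the stored values.
    """
    if not fits:
        raise ValueError("no fits to compare")
    hashes = {f.dataset_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were made against different datasets")
    if dataset is not None:
        from .core_data import dataset_fingerprint

        if hashes != {dataset_fingerprint(dataset)}:
            raise ValueError("fits do not match the supplied dataset")
    if m is None:
        if dataset is not None:
            m_eff = default_m(dataset)
        else:
            ms = {f.m for f in fits if f.m}
            if len(ms) != 1:
                raise ValueError("cannot infer m; pass dataset or m explicitly")
            m_eff = ms.pop()
    else:
        m_eff = m

    entries = []
    for f in fits:
        k = count_free_params(f.hypothesis)
        entries.append(
            {
                "hypothesis": f.hypothesis,
                "k": k,
                "v_min": f.v_min,
                "aicc": aicc(f.v_min, k, m_eff),
            }
        )
    best = min(e["aicc"] for e in entries)
    for e in entries:
        e["delta_aicc"] = e["aicc"] - best
    ranking = [
        e["hypothesis"]
        for e in sorted(entries, key=lambda e: (e["aicc"], e["hypothesis"]))
    ]
    return ComparisonReport(entries=entries, ranking=ranking, selected=ranking[0], m=m_eff)
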