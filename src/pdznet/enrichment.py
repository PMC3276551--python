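"""Hypergeometric over/under-representation of annotation classes.

Used for asking which of the 20 physiological disease classes (or any
other annotation scheme) is enriched among the proteins of a network
relative to a background proteome. Each class is tested independently —
no multiple-testing correction is applied, matching the convention of
reporting classes below a 0.05 display threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

DISPLAY_THRESHOLD = 0.05


class EnrichmentError(ValueError):
    pass


@dataclass
class AnnotationMap:
    """Class label -> annotated protein set, over a finite background."""

    classes: dict[str, set[str]] = field(default_factory=dict)
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        stray = {
            p for members in self.classes.values() for p in members
        } - self.background
        if stray:
            raise EnrichmentError(
                f"annotated proteins outside background: {sorted(stray)[:5]}"
            )


def hypergeometric_enrichment(
    members: set[str], annotations: AnnotationMap
) -> pd.DataFrame:
    """Exact tail probabilities per class for a protein set vs background.

    With population N = |background|, K = |class|, n = |members| and k the
    observed overlap: p_over = P(X >= k) and p_under = P(X <= k). The
    report carries counts, the fraction k/n, and whether p_over clears the
    0.05 display threshold.
    """
    stray = members - annotations.background
    if stray:
        raise EnrichmentError(f"members outside background: {sorted(stray)}")
    N, n = len(annotations.background), len(members)
    rows = []
    for label in sorted(annotations.classes):
        class_set = annotations.classes[label]
        K = len(class_set)
        k = len(members & class_set)
        dist = stats.hypergeom(N, K, n)
        rows.append(
            {
                "class": label,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fraction": k / n if n else 0.0,
                "p_over": float(dist.sf(k - 1)),
                "p_under": float(dist.cdf(k)),
                "displayed": float(dist.sf(k - 1)) < DISPLAY_THRESHOLD,
            }
        )
    return pd.DataFrame(rows)
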