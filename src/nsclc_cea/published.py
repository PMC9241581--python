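"""Published base-case totals of the original evaluation.

The packaged CSV holds the published discounted cost, QALY and LY totals of
the 12 strategies in both settings.  They serve as reference points for the
incremental analysis (ICERs, dominance classification, sequential ICERs can
be recomputed from them exactly) and as cross-checks of this package's own
model outputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .markov import CEResult

__all__ = ["load_published_base_case", "published_results"]


def load_published_base_case() -> pd.DataFrame:
    """Published per-arm totals (columns: country, arm, cost, qaly, ly)."""
    data = resources.files("nsclc_cea").joinpath("data/base_case_published.csv")
    with resources.as_file(data) as p:
        return pd.read_csv(p, comment="#")


def published_results(country: str) -> list[CEResult]:
    """Published totals of one setting as :class:`CEResult` objects."""
    df = load_published_base_case()
    sub = df[df["country"].str.lower() == country.lower()]
    if sub.empty:
        raise ValueError(f"no published results for country {country!r}")
    return [
        CEResult(arm=row.arm, cost=float(row.cost), qaly=float(row.qaly), ly=float(row.ly))
        for row in sub.itertuples()
    ]
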