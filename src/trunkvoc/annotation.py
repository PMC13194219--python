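"""Linear retention index (LRI) computation and library matching.

Experimental LRIs are computed from a co-analyzed n-alkane ladder
(nC5–nC17) by the van Den Dool & Kratz formula

    LRI(t) = 100·n + 100 · (t − t_n) / (t_{n+1} − t_n)

for the alkanes n, n+1 bracketing retention time t.  Features are then
matched to a reference library of compounds carrying literature LRIs,
compound classes and identification tiers (M = mass-spectral comparison,
R = retention-index comparison, S = confirmed with an analytical standard).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AlkaneLadder",
    "CompoundRecord",
    "compute_lri",
    "rt_from_lri",
    "match_library",
    "annotate_features",
    "load_ladder",
    "load_library",
]

COMPOUND_CLASSES = frozenset(
    {
        "MT",
        "SQT",
        "NCV",
        "aldehyde",
        "alcohol",
        "ketone",
        "ester",
        "carboxylic_acid",
        "aromatic_HC",
        "aliphatic_HC",
        "OCV_other",
    }
)


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane calibration ladder: (carbon number, retention time) pairs.

    Carbon numbers and retention times must both be strictly increasing.
    """

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("ladder needs at least two alkanes")
        ns = [n for n, _ in self.entries]
        ts = [t for _, t in self.entries]
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValueError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("retention times must be strictly increasing")

    @property
    def carbon_numbers(self) -> list[int]:
        return [n for n, _ in self.entries]

    @property
    def retention_times(self) -> list[float]:
        return [t for _, t in self.entries]


@dataclass(frozen=True)
class CompoundRecord:
    """A reference-library analyte."""

    name: str
    cas: str = ""
    formula: str = ""
    lri_lit: float | None = None
    compound_class: str = "OCV_other"
    id_tier: frozenset[str] = frozenset({"M"})

    def __post_init__(self) -> None:
        if self.lri_lit is not None and not self.lri_lit > 0:
            raise ValueError(f"{self.name}: lri_lit must be positive when present")
        if not self.id_tier:
            raise ValueError(f"{self.name}: id_tier must be non-empty")
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(f"{self.name}: unknown compound class {self.compound_class!r}")


def compute_lri(rt: float, ladder: AlkaneLadder, extrapolate: bool = False) -> float:
    """van Den Dool–Kratz linear retention index of a peak at *rt* minutes.

    By default retention times outside the ladder span are an error; with
    ``extrapolate=True`` the terminal segment's slope is extended, which
    allows indices below 100·n_min (the study reports e.g. LRI < 500 for
    2-methylbutane eluting before nC5).
    """
    ts = ladder.retention_times
    ns = ladder.carbon_numbers
    if not extrapolate and (rt < ts[0] or rt > ts[-1]):
        raise ValueError(
            f"retention time {rt} outside ladder span [{ts[0]}, {ts[-1]}]"
        )
    # bracketing segment index; clamp to terminal segments when extrapolating
    i = bisect.bisect_right(ts, rt) - 1
    i = max(0, min(i, len(ts) - 2))
    n_lo, n_hi = ns[i], ns[i + 1]
    t_lo, t_hi = ts[i], ts[i + 1]
    return 100.0 * n_lo + 100.0 * (n_hi - n_lo) * (rt - t_lo) / (t_hi - t_lo)


def rt_from_lri(lri: float, ladder: AlkaneLadder, extrapolate: bool = False) -> float:
    """Inverse of :func:`compute_lri`: the retention time at a given index."""
    ts = ladder.retention_times
    ns = ladder.carbon_numbers
    idx = [100.0 * n for n in ns]
    if not extrapolate and (lri < idx[0] or lri > idx[-1]):
        raise ValueError(f"LRI {lri} outside ladder span [{idx[0]}, {idx[-1]}]")
    i = bisect.bisect_right(idx, lri) - 1
    i = max(0, min(i, len(idx) - 2))
    frac = (lri - idx[i]) / (idx[i + 1] - idx[i])
    return ts[i] + frac * (ts[i + 1] - ts[i])


def match_library(
    lri_exp: float,
    library: list[CompoundRecord],
    tolerance: float = 15.0,
) -> list[tuple[CompoundRecord, float]]:
    """Rank library compounds by |LRI_exp − LRI_lit| within *tolerance*.

    Returns ``(record, delta)`` pairs sorted by ascending |delta|, ties
    broken lexicographically by name.  An empty list is a valid outcome.
    Compounds without a literature LRI cannot be matched by index and are
    skipped.
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be > 0")
    hits = []
    for rec in library:
        if rec.lri_lit is None:
            continue
        delta = lri_exp - rec.lri_lit
        if abs(delta) <= tolerance:
            hits.append((rec, delta))
    hits.sort(key=lambda h: (abs(h[1]), h[0].name))
    return hits


def annotate_features(
    features: pd.DataFrame,
    ladder: AlkaneLadder,
    library: list[CompoundRecord],
    tolerance: float = 15.0,
    extrapolate: bool = False,
) -> pd.DataFrame:
    """Annotate a feature table (feature_id, rt_min) with LRIs and best matches.

    Returns one row per unique feature_id with columns
    ``feature_id, rt_min, lri_exp, best_match, delta_lri, compound_class,
    id_tier`` (best_match empty when nothing lies within tolerance).
    """
    rows = []
    per_feature = (
        features.groupby("feature_id", sort=True)["rt_min"].median().reset_index()
    )
    for row in per_feature.itertuples(index=False):
        lri = compute_lri(float(row.rt_min), ladder, extrapolate=extrapolate)
        hits = match_library(lri, library, tolerance)
        if hits:
            best, delta = hits[0]
            rows.append(
                {
                    "feature_id": row.feature_id,
                    "rt_min": row.rt_min,
                    "lri_exp": lri,
                    "best_match": best.name,
                    "delta_lri": delta,
                    "compound_class": best.compound_class,
                    "id_tier": "".join(sorted(best.id_tier)),
                }
            )
        else:
            rows.append(
                {
                    "feature_id": row.feature_id,
                    "rt_min": row.rt_min,
                    "lri_exp": lri,
                    "best_match": "",
                    "delta_lri": float("nan"),
                    "compound_class": "",
                    "id_tier": "",
                }
            )
    return pd.DataFrame(rows)


def load_ladder(path) -> AlkaneLadder:
    df = pd.read_csv(path).sort_values("carbon_number")
    return AlkaneLadder(
        tuple((int(r.carbon_number), float(r.rt_min)) for r in df.itertuples())
    )


def load_library(path) -> list[CompoundRecord]:
    df = pd.read_csv(path)
    records = []
    for r in df.itertuples(index=False):
        lri = getattr(r, "lri_lit", None)
        records.append(
            CompoundRecord(
                name=str(r.name),
                cas=str(getattr(r, "cas", "") or ""),
                formula=str(getattr(r, "formula", "") or ""),
                lri_lit=float(lri) if lri is not None and pd.notna(lri) else None,
                compound_class=str(r.compound_class),
                id_tier=frozenset(str(r.id_tier)),
            )
        )
    return records
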