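"""Detection-frequency filters and fold-change classification of volatiles.

Each compound that survives the detection-frequency (DF) retention filter is
assigned one primary label:

* ``constitutive`` — detected in >= 50% of every tree's measurements before
  the biotic-stress phase (phases 1–2): a continuously emitted core volatile.
* ``stress_induced`` — emission increased >= twofold, and to a comparable
  extent, in both the infested tree and its neighbor after stress onset.
* ``hipv`` — herbivore-induced: appeared de novo at the infested tree after
  beetle exposure, or increased >= twofold versus both its own pre-exposure
  phase and the two non-infested trees.
* ``neighbor_induced`` — the mirror rule with the neighbor tree as numerator.
* ``unclassified`` — none of the rules fired.

A constitutive compound whose emission additionally satisfies an induced
rule keeps ``constitutive`` as its primary label and carries the induced
rule as a secondary flag, so the primary labels always partition the
retained set.

Sparse scopes are handled through symbolic ratio marks mirroring the report
conventions: an inter-tree ratio is marked with the emitting tree's name
(e.g. ``"ApI"``) when the compound was never detected at the comparison
trees, with ``">"`` when it appeared in fewer than 20% of the comparison
measurements, and an intra-tree post/pre ratio is marked ``"ALB"`` when the
compound appeared de novo (detected in < 20% of pre-exposure measurements).
Means entering any ratio require DF >= 20% in that (tree, period) scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .study import DEFAULT_PHASES, assign_phase

__all__ = [
    "TreeRoles",
    "RatioMark",
    "DetectionProfile",
    "ClassificationResult",
    "EmissionContext",
    "detection_frequency",
    "retention_filter",
    "constitutive_set",
    "phase_mean_rate",
    "ratio_with_marks",
    "classify_compound",
    "classify_all",
    "classification_to_frame",
]

LABELS = ("constitutive", "hipv", "neighbor_induced", "stress_induced", "unclassified")

PRE_PHASES = frozenset({1, 2})
POST_PHASES = frozenset({3})


@dataclass(frozen=True)
class TreeRoles:
    """Maps study roles to tree ids (exactly one tree per role)."""

    control: str = "ApC"
    infested: str = "ApI"
    neighbor: str = "ApN"

    def __post_init__(self) -> None:
        if len({self.control, self.infested, self.neighbor}) != 3:
            raise ValueError("control, infested and neighbor must be distinct trees")

    @property
    def all(self) -> tuple[str, str, str]:
        return (self.control, self.infested, self.neighbor)


@dataclass(frozen=True)
class RatioMark:
    """A fold-change ratio or its symbolic stand-in for sparse scopes."""

    kind: str  # numeric | exclusive | sparse | de_novo | undefined
    value: float | None = None
    label: str = ""

    def render(self) -> str:
        if self.kind == "numeric":
            return f"{self.value:.2f}"
        if self.kind == "exclusive":
            return self.label
        if self.kind == "sparse":
            return ">"
        if self.kind == "de_novo":
            return "ALB"
        return ""

    def satisfies_twofold(self) -> bool:
        """Does this ratio count as a >= twofold increase?

        Symbolic marks (exclusive / sparse comparison scope, de novo
        appearance) count as satisfied: the denominator was essentially
        absent.
        """
        if self.kind == "numeric":
            return self.value >= 2.0
        return self.kind in ("exclusive", "sparse", "de_novo")


@dataclass
class DetectionProfile:
    """Per-compound detection frequencies over (tree, phase-set) scopes."""

    compound: str
    df: dict = field(default_factory=dict)  # (tree, frozenset phases) -> %
    n: dict = field(default_factory=dict)  # (tree, frozenset phases) -> count


@dataclass
class ClassificationResult:
    compound: str
    label: str
    secondary: str = ""
    rule: str = ""
    profile: DetectionProfile | None = None
    ratios: dict = field(default_factory=dict)  # name -> RatioMark


class EmissionContext:
    """Joins an emission table with the sample design for DF bookkeeping.

    The DF denominator is the number of *samples in scope* (detected or
    not), so the context needs the full design, not just the detections.
    Consecutive same-day duplicates count as separate samples.
    """

    def __init__(self, emissions: pd.DataFrame, design: pd.DataFrame, phases=DEFAULT_PHASES):
        design = design[~design["is_background"].astype(bool)].copy()
        design["phase"] = design["day"].map(lambda d: assign_phase(int(d), phases))
        self.design = design
        self.phases = phases
        emissions = emissions.copy()
        emissions["phase"] = emissions["day"].map(lambda d: assign_phase(int(d), phases))
        self.emissions = emissions
        # sample key = (tree, day, replicate)
        self._detected = {
            compound: set(zip(grp["tree_id"], grp["day"], grp["replicate"]))
            for compound, grp in emissions.groupby("compound")
        }

    @property
    def compounds(self) -> list[str]:
        return sorted(self._detected)

    def samples_in_scope(self, trees, phases) -> pd.DataFrame:
        d = self.design
        return d[d["tree_id"].isin(set(trees)) & d["phase"].isin(set(phases))]

    def n_samples(self, trees, phases) -> int:
        return len(self.samples_in_scope(trees, phases))

    def n_detected(self, compound: str, trees, phases) -> int:
        scope = self.samples_in_scope(trees, phases)
        detected = self._detected.get(compound, set())
        keys = zip(scope["tree_id"], scope["day"], scope["replicate"])
        return sum(1 for k in keys if k in detected)

    def rates(self, compound: str, tree: str, phases) -> pd.Series:
        e = self.emissions
        sel = (
            (e["compound"] == compound)
            & (e["tree_id"] == tree)
            & (e["phase"].isin(set(phases)))
        )
        return e.loc[sel, "rate"]

    def unit_of(self, compound: str) -> str:
        units = self.emissions.loc[self.emissions["compound"] == compound, "unit"]
        uniq = units.unique()
        if len(uniq) > 1:
            raise ValueError(f"{compound}: mixed rate units {sorted(uniq)}")
        return str(uniq[0])


def detection_frequency(ctx: EmissionContext, compound: str, trees, phases) -> float:
    """DF in % = 100 × detected samples / samples in scope (duplicates count)."""
    n = ctx.n_samples(trees, phases)
    if n == 0:
        raise ValueError(f"empty scope trees={sorted(trees)} phases={sorted(phases)}")
    return 100.0 * ctx.n_detected(compound, trees, phases) / n


def retention_filter(ctx: EmissionContext, threshold: float = 10.0) -> list[str]:
    """Compounds with pooled DF >= threshold over all trunk samples (inclusive)."""
    trees = set(ctx.design["tree_id"])
    phases = {p.phase_id for p in ctx.phases}
    return [
        c
        for c in ctx.compounds
        if detection_frequency(ctx, c, trees, phases) >= threshold
    ]


def constitutive_set(
    ctx: EmissionContext,
    compounds,
    roles: TreeRoles,
    threshold: float = 50.0,
    pooled: bool = False,
) -> set[str]:
    """Core volatiles: DF >= threshold before biotic stress (phases 1–2).

    By default the threshold must hold in *every* tree separately; with
    ``pooled=True`` a single DF over all trees' phase-1–2 samples is used.
    """
    result = set()
    for compound in compounds:
        if pooled:
            ok = detection_frequency(ctx, compound, roles.all, PRE_PHASES) >= threshold
        else:
            ok = all(
                detection_frequency(ctx, compound, [t], PRE_PHASES) >= threshold
                for t in roles.all
            )
        if ok:
            result.add(compound)
    return result


def phase_mean_rate(
    ctx: EmissionContext, compound: str, tree: str, phases, min_df: float = 20.0
) -> float | None:
    """Mean emission rate over detected observations, or None when too sparse.

    Only (tree, period) scopes where the compound reached DF >= ``min_df``
    contribute a mean; sparser scopes are undefined and trigger symbolic
    ratio marks downstream.
    """
    if detection_frequency(ctx, compound, [tree], phases) < min_df:
        return None
    rates = ctx.rates(compound, tree, phases)
    if rates.empty:
        return None
    return float(rates.mean())


def ratio_with_marks(
    numerator_mean: float | None,
    denominator_mean: float | None,
    numerator_exclusive: bool = False,
    intra_tree: bool = False,
    numerator_label: str = "",
) -> RatioMark:
    """Fold-change ratio with report-style symbolic marks.

    Numeric when both means are defined.  When only the numerator is
    defined: ``"ALB"`` (de novo) for intra-tree post/pre comparisons, the
    numerator tree's label for compounds exclusive to it, and ``">"`` when
    the comparison scope was merely sparse (< 20% DF).
    """
    if numerator_mean is None and denominator_mean is None:
        raise ValueError("both ratio terms undefined; compound should not reach here")
    if numerator_mean is None:
        return RatioMark(kind="undefined")
    if denominator_mean is not None:
        if denominator_mean <= 0:
            return RatioMark(kind="sparse")
        return RatioMark(kind="numeric", value=numerator_mean / denominator_mean)
    if intra_tree:
        return RatioMark(kind="de_novo")
    if numerator_exclusive:
        return RatioMark(kind="exclusive", label=numerator_label)
    return RatioMark(kind="sparse")


def _is_de_novo(ctx: EmissionContext, compound: str, tree: str, min_df: float = 20.0) -> bool:
    """De novo: DF < min_df before exposure and >= min_df after."""
    pre = detection_frequency(ctx, compound, [tree], PRE_PHASES)
    post = detection_frequency(ctx, compound, [tree], POST_PHASES)
    return pre < min_df and post >= min_df


def _never_detected(ctx: EmissionContext, compound: str, trees) -> bool:
    all_phases = {p.phase_id for p in ctx.phases}
    return all(ctx.n_detected(compound, [t], all_phases) == 0 for t in trees)


def _build_ratios(
    ctx: EmissionContext, compound: str, roles: TreeRoles, min_df: float
) -> dict[str, RatioMark]:
    """All inter- and intra-tree ratios entering the induced rules."""
    means = {
        (t, "post"): phase_mean_rate(ctx, compound, t, POST_PHASES, min_df)
        for t in roles.all
    }
    means.update(
        {
            (t, "pre"): phase_mean_rate(ctx, compound, t, PRE_PHASES, min_df)
            for t in roles.all
        }
    )
    inf, nbr, ctl = roles.infested, roles.neighbor, roles.control
    ratios: dict[str, RatioMark] = {}

    def inter(name, num_tree, den_tree):
        num = means[(num_tree, "post")]
        if num is None:
            ratios[name] = RatioMark(kind="undefined")
            return
        ratios[name] = ratio_with_marks(
            num,
            means[(den_tree, "post")],
            numerator_exclusive=_never_detected(ctx, compound, [t for t in roles.all if t != num_tree]),
            numerator_label=num_tree,
        )

    def intra(name, tree):
        num = means[(tree, "post")]
        if num is None:
            ratios[name] = RatioMark(kind="undefined")
            return
        ratios[name] = ratio_with_marks(num, means[(tree, "pre")], intra_tree=True)

    inter(f"{inf}/{nbr}", inf, nbr)
    inter(f"{inf}/{ctl}", inf, ctl)
    inter(f"{nbr}/{inf}", nbr, inf)
    inter(f"{nbr}/{ctl}", nbr, ctl)
    intra(f"post/pre@{inf}", inf)
    intra(f"post/pre@{nbr}", nbr)
    return ratios


def _stress_rule(ratios: dict[str, RatioMark], band: float, roles: TreeRoles) -> bool:
    """Twofold increase of comparable extent in both infested and neighbor.

    Comparability: the two intra-tree increase ratios within a factor-``band``
    window of each other when both are numeric; two de-novo appearances also
    count as comparable.  A numeric/symbolic mix is not comparable.
    """
    r_i = ratios[f"post/pre@{roles.infested}"]
    r_n = ratios[f"post/pre@{roles.neighbor}"]
    if not (r_i.satisfies_twofold() and r_n.satisfies_twofold()):
        return False
    if r_i.kind == "numeric" and r_n.kind == "numeric":
        q = r_i.value / r_n.value
        return 1.0 / band <= q <= band
    return r_i.kind == "de_novo" and r_n.kind == "de_novo"


def _induced_rule(
    ctx, compound, roles, ratios, tree: str, vs: tuple[str, str], min_df: float
) -> str:
    """HIPV / neighbor-induced rule for ``tree`` against comparison trees.

    Returns the name of the branch that fired ("de_novo", "twofold") or "".
    """
    if _is_de_novo(ctx, compound, tree, min_df):
        return "de_novo"
    intra = ratios[f"post/pre@{tree}"]
    inters = [ratios[f"{tree}/{v}"] for v in vs]
    if intra.satisfies_twofold() and all(r.satisfies_twofold() for r in inters):
        return "twofold"
    return ""


def classify_compound(
    ctx: EmissionContext,
    compound: str,
    roles: TreeRoles,
    constitutive: set[str],
    min_df: float = 20.0,
    fold: float = 2.0,
    band: float = 2.0,
) -> ClassificationResult:
    """Assign the primary (and any secondary) class label to one compound.

    Rule priority: constitutive → stress_induced → hipv → neighbor_induced
    → unclassified.  ``fold`` is fixed at 2 by the twofold rules encoded in
    :class:`RatioMark`; it is exposed for transparency only.
    """
    ratios = _build_ratios(ctx, compound, roles, min_df)
    profile = DetectionProfile(compound=compound)
    for tree in roles.all:
        for name, phases in (("pre", PRE_PHASES), ("post", POST_PHASES)):
            key = (tree, name)
            profile.df[key] = detection_frequency(ctx, compound, [tree], phases)
            profile.n[key] = ctx.n_samples([tree], phases)

    inf, nbr, ctl = roles.infested, roles.neighbor, roles.control

    def induced_label() -> tuple[str, str]:
        if _stress_rule(ratios, band, roles):
            return "stress_induced", "stress"
        branch = _induced_rule(ctx, compound, roles, ratios, inf, (nbr, ctl), min_df)
        if branch:
            return "hipv", f"hipv_{branch}"
        branch = _induced_rule(ctx, compound, roles, ratios, nbr, (inf, ctl), min_df)
        if branch:
            return "neighbor_induced", f"neighbor_{branch}"
        return "", ""

    if compound in constitutive:
        secondary, rule = induced_label()
        return ClassificationResult(
            compound=compound,
            label="constitutive",
            secondary=secondary,
            rule=rule or "constitutive_df50",
            profile=profile,
            ratios=ratios,
        )
    label, rule = induced_label()
    if not label:
        label, rule = "unclassified", "none"
    return ClassificationResult(
        compound=compound,
        label=label,
        rule=rule,
        profile=profile,
        ratios=ratios,
    )


def classify_all(
    ctx: EmissionContext,
    roles: TreeRoles,
    retention_threshold: float = 10.0,
    constitutive_threshold: float = 50.0,
    min_df: float = 20.0,
    band: float = 2.0,
    pooled_constitutive: bool = False,
) -> list[ClassificationResult]:
    """Run the full filter-and-classify cascade over every detected compound."""
    retained = retention_filter(ctx, retention_threshold)
    core = constitutive_set(
        ctx, retained, roles, constitutive_threshold, pooled=pooled_constitutive
    )
    return [
        classify_compound(ctx, c, roles, core, min_df=min_df, band=band)
        for c in retained
    ]


def classification_to_frame(results: list[ClassificationResult]) -> pd.DataFrame:
    """Flatten classification results to the `classification.csv` layout."""
    rows = []
    for r in results:
        row = {
            "compound": r.compound,
            "label": r.label,
            "secondary_flag": r.secondary,
            "rule": r.rule,
        }
        if r.profile is not None:
            for (tree, period), df in sorted(r.profile.df.items()):
                row[f"df_{tree}_{period}"] = df
        for name, mark in r.ratios.items():
            row[f"ratio_{name}"] = mark.render()
        rows.append(row)
    return pd.DataFrame(rows)
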