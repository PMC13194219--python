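"""Synthetic three-tree trunk-volatile study generator.

No dataset accompanies the study design this package analyzes, so every
pipeline stage is exercised on synthetic data that emulates its structure:
three Norway-maple trees — a control (``ApC``), a beetle-infested tree
(``ApI``) and an adjacent non-infested neighbor (``ApN``) — sampled in
duplicate on ~42 days across a 188-day window split into acclimation
(days 0–8), abiotic-stress (9–19, relocation into quarantine) and
biotic-stress (20–188) phases.  The control is only sampled through day 138
(declining vitality in the emulated design).

Planted compounds carry a known true class label.  The mean emission of
compound *c* at tree *t* on day *d* is

    baseline_t · stress_multiplier(t, d)  +  Σ_k kernel_k(d)

where each kernel is an 'Extreme' peak (sums of kernels produce the double
and triple peaks seen in real induction dynamics).  Observed rates are the
mean times a unit-mean multiplicative lognormal noise factor (default
CV 0.2), drawn independently per replicate; observations below the
detection threshold are censored, i.e. the row is simply absent — censoring
never writes a zero area.  Retention times are back-computed from each
compound's true retention index through the n-alkane ladder, and component
areas are back-computed through the calibration line that the downstream
pipeline will use, so quantification round-trips exactly.

A handful of ubiquitous ambient features (appearing at matching levels in
trunk and background samples) exercise the background filter; they carry no
true label and are expected to be removed before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AlkaneLadder, rt_from_lri
from .classify import TreeRoles
from .dynamics import ExtremeParams, eval_extreme
from .study import DEFAULT_PHASES, assign_phase

__all__ = [
    "PlantedCompound",
    "GeneratorConfig",
    "default_compounds",
    "default_config",
    "generate_study",
    "truth_table",
    "write_study",
]

LABELS5 = ("constitutive", "hipv", "neighbor_induced", "stress_induced", "unclassified")


@dataclass
class PlantedCompound:
    """A compound planted into the synthetic study with a known class.

    ``quant`` selects the quantification route: ``"own"`` (its own
    calibration standard), the name of a surrogate compound, or ``""``
    (no standard; stays in area units).
    """

    name: str
    compound_class: str
    true_label: str
    baseline: dict = field(default_factory=dict)  # tree -> rate
    kernels: dict = field(default_factory=dict)  # tree -> list[ExtremeParams]
    stress_multiplier: float = 1.0
    lri_true: float = 1000.0
    quant: str = "own"
    calibration_slope: float = 1e5  # counts per ng
    calibration_intercept: float = 500.0
    de_novo: bool = False


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the synthetic generator."""

    seed: int = 0
    window_days: int = 188
    control_last_day: int = 138
    days_per_phase: tuple = (7, 4, 31)  # denser sampling early
    roles: TreeRoles = field(default_factory=TreeRoles)
    phases: tuple = DEFAULT_PHASES
    compounds: list = field(default_factory=list)
    noise_cv: float = 0.2
    detection_threshold: float = 0.1  # rate units
    bark_area_dm2: float = 2.0
    duration_h: float = 1.5
    flow_ml_min: float = 30.0
    background_every: int = 4  # one background per location every k-th day

    def __post_init__(self) -> None:
        if not self.compounds:
            self.compounds = default_compounds()
        self.validate()

    def validate(self) -> None:
        roles = self.roles
        for c in self.compounds:
            trees_with_kernels = {t for t, ks in c.kernels.items() if ks}
            if c.true_label == "hipv":
                if trees_with_kernels - {roles.infested}:
                    raise ValueError(
                        f"{c.name}: hipv compounds may only carry kernels on "
                        f"the infested tree"
                    )
                if not c.de_novo and c.baseline.get(roles.infested, 0.0) <= 0:
                    raise ValueError(
                        f"{c.name}: upregulated hipv needs a pre-exposure "
                        "baseline at the infested tree"
                    )
            elif c.true_label == "neighbor_induced":
                if trees_with_kernels - {roles.neighbor}:
                    raise ValueError(
                        f"{c.name}: neighbor-induced compounds may only carry "
                        "kernels on the neighbor tree"
                    )
            elif c.true_label == "stress_induced":
                if trees_with_kernels != {roles.infested, roles.neighbor}:
                    raise ValueError(
                        f"{c.name}: stress-induced compounds need kernels on "
                        "both infested and neighbor trees"
                    )
            elif c.true_label == "constitutive":
                low = [t for t in roles.all if c.baseline.get(t, 0.0) <= 0]
                if low:
                    raise ValueError(
                        f"{c.name}: constitutive compounds need positive "
                        f"baselines on every tree (missing on {low})"
                    )


def _alkane_ladder() -> AlkaneLadder:
    # mildly nonlinear synthetic ladder, nC5 through nC17
    return AlkaneLadder(
        tuple(
            (n, round(1.2 + 1.55 * (n - 5) + 0.015 * (n - 5) ** 2, 4))
            for n in range(5, 18)
        )
    )


def _kernel(tree_amp: float, xc: float, w: float) -> ExtremeParams:
    return ExtremeParams(y0=0.0, A=tree_amp, xc=xc, w=w)


def default_compounds() -> list[PlantedCompound]:
    """The default planted panel: 30 constitutive, 15 herbivore-induced
    (5 de novo), 6 neighbor-induced and 4 stress-induced compounds.

    Baselines, stress multipliers and kernel timings follow the archetypes
    of the emulated study: relocation-sensitive monoterpenoids, an early
    monoterpenoid induction wave (~2 weeks post-exposure), a late, broad
    sesquiterpenoid wave (~10 weeks), nitrile emissions exclusive to the
    infested tree, and delayed neighbor-tree sesquiterpene peaks (~8 weeks).
    """
    I, N, C = "ApI", "ApN", "ApC"
    out: list[PlantedCompound] = []

    # --- constitutive core (30): aldehyde-dominated, plus HCs, MTs, OCVs ---
    consti = [
        # name, class, baseline, stress multiplier, ApI kernel amp (secondary)
        ("2-methylpropanal", "aldehyde", 0.5, 1.2, 0.0),
        ("2-methylbutanal", "aldehyde", 0.9, 1.2, 8.0),
        ("pentanal", "aldehyde", 1.8, 1.2, 0.0),
        ("hexanal", "aldehyde", 14.0, 1.5, 0.0),
        ("2,2-dimethylpentanal", "aldehyde", 0.45, 1.1, 0.0),
        ("heptanal", "aldehyde", 2.7, 1.2, 0.0),
        ("benzaldehyde", "aldehyde", 4.4, 1.3, 0.0),
        ("octanal", "aldehyde", 5.8, 1.2, 0.0),
        ("nonanal", "aldehyde", 18.8, 1.2, 0.0),
        ("decanal", "aldehyde", 6.0, 1.2, 8.0),
        ("pentane", "aliphatic_HC", 0.8, 1.0, 0.0),
        ("hexane", "aliphatic_HC", 0.6, 1.0, 0.0),
        ("nonane", "aliphatic_HC", 1.1, 1.0, 0.0),
        ("decane", "aliphatic_HC", 0.9, 1.0, 0.0),
        ("undecane", "aliphatic_HC", 0.7, 1.0, 0.0),
        ("dodecane", "aliphatic_HC", 0.5, 1.0, 0.0),
        ("tridecane", "aliphatic_HC", 0.3, 1.0, 0.0),
        ("tetradecane", "aliphatic_HC", 0.25, 1.3, 0.0),
        ("o-xylene", "aromatic_HC", 0.4, 1.0, 0.0),
        ("1,2,4-trimethylbenzene", "aromatic_HC", 0.35, 1.4, 0.0),
        ("1-hexanol", "alcohol", 0.2, 1.1, 0.0),
        ("2-ethyl-1-hexanol", "alcohol", 0.8, 1.4, 0.0),
        ("2-butanone", "ketone", 1.2, 1.1, 10.0),
        ("acetophenone", "ketone", 0.16, 1.1, 0.0),
        ("6-methyl-5-hepten-2-one", "ketone", 0.3, 1.2, 0.0),
        ("acetic acid", "carboxylic_acid", 0.6, 1.2, 0.0),
        ("alpha-pinene", "MT", 1.5, 6.0, 0.0),
        ("beta-pinene", "MT", 0.8, 4.0, 0.0),
        ("3-carene", "MT", 1.0, 6.0, 0.0),
        ("limonene", "MT", 0.9, 1.5, 6.0),
    ]
    for name, klass, base, mult, amp in consti:
        out.append(
            PlantedCompound(
                name=name,
                compound_class=klass,
                true_label="constitutive",
                baseline={C: base, I: base, N: base},
                stress_multiplier=mult,
                kernels={I: [_kernel(amp, 45.0, 15.0)]} if amp > 0 else {},
            )
        )

    # --- herbivore-induced (15): 10 upregulated + 5 de novo ---
    # upregulated: pre-exposure baseline at ApI only; early MT wave and one
    # late SQT; amplitudes ~30x baseline so post/pre and inter-tree ratios
    # clear twofold with margin
    hipv_up = [
        # name, class, ApI baseline, kernels (amp-mult, xc, w)...
        ("tricyclene", "MT", 0.5, [(30, 34, 8), (12, 70, 8)]),
        ("alpha-thujene", "MT", 0.4, [(30, 34, 8)]),
        ("camphene", "MT", 1.1, [(30, 30, 7), (16, 55, 7), (10, 80, 7)]),
        ("sabinene", "MT", 0.7, [(28, 33, 9), (14, 60, 9)]),
        ("beta-myrcene", "MT", 0.5, [(28, 33, 9), (14, 60, 9)]),
        ("p-cymene", "MT", 2.0, [(32, 32, 8), (18, 58, 9)]),
        ("gamma-terpinene", "MT", 1.2, [(30, 32, 8), (16, 58, 9)]),
        ("beta-ocimene", "MT", 0.8, [(26, 35, 6)]),
        ("DMNT", "MT", 0.9, [(30, 34, 6)]),
        ("alpha-longipinene", "SQT", 0.6, [(24, 26, 6), (20, 62, 8), (16, 84, 8)]),
    ]
    for name, klass, base, kernels in hipv_up:
        out.append(
            PlantedCompound(
                name=name,
                compound_class=klass,
                true_label="hipv",
                baseline={I: base, N: 0.04, C: 0.0},
                kernels={I: [_kernel(m * base, xc, w) for m, xc, w in kernels]},
            )
        )
    # de novo: no pre-exposure baseline anywhere; late broad SQT wave and
    # two infested-tree-exclusive nitriles (quantified in area units)
    hipv_dn = [
        ("cyclosativene", "SQT", [(10.0, 70, 14)], "own"),
        ("alpha-copaene", "SQT", [(9.0, 72, 14)], "own"),
        ("(E)-beta-caryophyllene", "SQT", [(8.0, 75, 14)], "own"),
        ("isobutyronitrile", "NCV", [(8.0, 55, 14)], ""),
        ("2-methylbutanenitrile", "NCV", [(6.0, 60, 14)], ""),
    ]
    for name, klass, kernels, quant in hipv_dn:
        out.append(
            PlantedCompound(
                name=name,
                compound_class=klass,
                true_label="hipv",
                baseline={},
                kernels={I: [_kernel(a, xc, w) for a, xc, w in kernels]},
                quant=quant,
                de_novo=True,
            )
        )

    # --- neighbor-induced (6): 3 de novo SQT-like, 3 upregulated at ApN ---
    nbr = [
        ("(Z)-alpha-bergamotene", "SQT", 0.0, [(6.0, 76, 14)], True),
        ("alpha-santalene", "SQT", 0.0, [(10.0, 45, 9), (8.0, 95, 14)], True),
        ("cuparene", "SQT", 0.0, [(10.0, 47, 9), (8.0, 97, 14)], True),
        ("2-heptanone", "ketone", 0.5, [(15, 90, 35)], False),
        ("1-penten-3-ol", "alcohol", 0.4, [(20, 120, 18)], False),
        ("2,4-dimethyl-1-heptene", "aliphatic_HC", 0.4, [(20, 95, 16)], False),
    ]
    for name, klass, base, kernels, dn in nbr:
        baseline = {} if dn else {"ApN": base, "ApI": 0.04, "ApC": 0.0}
        amp = 1.0 if dn else base
        out.append(
            PlantedCompound(
                name=name,
                compound_class=klass,
                true_label="neighbor_induced",
                baseline=baseline,
                kernels={N: [_kernel(m * amp, xc, w) for m, xc, w in kernels]},
                de_novo=dn,
            )
        )

    # --- stress-induced (4): comparable twofold increases at ApI and ApN ---
    stress = [
        ("benzyl alcohol", "alcohol", 0.4, 15, 40, 48, 12),
        ("3-methylbutanal", "aldehyde", 0.5, 12, 38, 46, 12),
        ("styrene", "aromatic_HC", 0.4, 14, 42, 50, 12),
        ("propylbenzene", "aromatic_HC", 0.3, 12, 44, 52, 12),
    ]
    for name, klass, base, mult, xc_i, xc_n, w in stress:
        out.append(
            PlantedCompound(
                name=name,
                compound_class=klass,
                true_label="stress_induced",
                baseline={I: base, N: base, C: 0.0},
                kernels={
                    I: [_kernel(mult * base, xc_i, w)],
                    N: [_kernel(mult * base, xc_n, w)],
                },
            )
        )

    # deterministic retention-index grid (spacing 20, inside the nC5–nC17
    # ladder span) and per-compound calibration lines
    for i, c in enumerate(out):
        c.lri_true = 560.0 + 20.0 * i
        c.calibration_slope = 5e4 * (1 + (i % 9))
        c.calibration_intercept = 200.0 + 50.0 * (i % 7)
    # tentatively quantified terpenoids: structurally related surrogates
    surrogate_of = {
        "tricyclene": "alpha-pinene",
        "alpha-thujene": "alpha-pinene",
        "sabinene": "beta-pinene",
        "gamma-terpinene": "limonene",
        "DMNT": "beta-myrcene",
        "cyclosativene": "alpha-longipinene",
        "(Z)-alpha-bergamotene": "alpha-longipinene",
        "alpha-santalene": "alpha-longipinene",
    }
    for c in out:
        if c.name in surrogate_of:
            c.quant = surrogate_of[c.name]
    return out


#: Ubiquitous ambient features planted to exercise the background filter:
#: (name, lri_true, trunk/background area level in 1e6-count rate units).
UBIQUITOUS = (
    ("toluene", 510.0, 2.0),
    ("methyl acetate", 525.0, 1.0),
    ("m-xylene", 540.0, 1.5),
)


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    return GeneratorConfig(seed=seed, **overrides)


def _sampling_days(cfg: GeneratorConfig, rng: np.random.Generator) -> list[int]:
    spans = [(0, 8), (9, 19), (20, cfg.window_days)]
    days: list[int] = []
    for (lo, hi), k in zip(spans, cfg.days_per_phase):
        pool = np.arange(lo, hi + 1)
        days.extend(sorted(rng.choice(pool, size=min(k, len(pool)), replace=False)))
    return [int(d) for d in days]


def _noise_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _quant_curve(c: PlantedCompound, by_name: dict) -> tuple[float, float] | None:
    """(slope, intercept) of the curve the pipeline will quantify *c* with."""
    if c.quant == "own":
        return c.calibration_slope, c.calibration_intercept
    if c.quant == "":
        return None
    surr = by_name[c.quant]
    return surr.calibration_slope, surr.calibration_intercept


def generate_study(cfg: GeneratorConfig) -> dict[str, pd.DataFrame]:
    """Generate the full synthetic study as a dict of plain tables.

    Returns ``design``, ``peaks``, ``alkanes``, ``library``, ``calibration``,
    ``surrogates`` and ``truth``.  Byte-identical for a fixed config and
    seed.  The truth table is consumed only by tests and scoring, never by
    the pipeline itself.
    """
    rng = np.random.default_rng(cfg.seed)
    roles = cfg.roles
    ladder = _alkane_ladder()
    days = _sampling_days(cfg, rng)
    by_name = {c.name: c for c in cfg.compounds}

    # --- design table ------------------------------------------------------
    design_rows = []
    counter = 0
    tree_days = {
        roles.control: [d for d in days if d <= cfg.control_last_day],
        roles.infested: days,
        roles.neighbor: days,
    }

    def location_of(tree: str, day: int) -> str:
        if tree == roles.control:
            return "outside"
        return "outside" if assign_phase(day, cfg.phases) == 1 else "inside_quarantine"

    for tree in roles.all:
        for day in tree_days[tree]:
            for rep in (1, 2):
                counter += 1
                design_rows.append(
                    {
                        "sample_id": f"S{counter:04d}",
                        "tree_id": tree,
                        "day": day,
                        "replicate": rep,
                        "bark_area_dm2": cfg.bark_area_dm2,
                        "duration_h": cfg.duration_h,
                        "flow_ml_min": cfg.flow_ml_min,
                        "is_background": False,
                        "location": location_of(tree, day),
                    }
                )
    # background samples, one per location on every k-th sampling day
    for i, day in enumerate(days):
        if i % cfg.background_every:
            continue
        for location in ("outside", "inside_quarantine"):
            if location == "inside_quarantine" and assign_phase(day, cfg.phases) == 1:
                continue  # quarantine not yet in use during acclimation
            counter += 1
            design_rows.append(
                {
                    "sample_id": f"S{counter:04d}",
                    "tree_id": "BG",
                    "day": day,
                    "replicate": 1,
                    "bark_area_dm2": float("nan"),
                    "duration_h": cfg.duration_h,
                    "flow_ml_min": cfg.flow_ml_min,
                    "is_background": True,
                    "location": location,
                }
            )
    design = pd.DataFrame(design_rows)

    # --- reference tables --------------------------------------------------
    ordered = sorted(cfg.compounds, key=lambda c: c.lri_true)
    feature_of = {c.name: f"F{i + 1:03d}" for i, c in enumerate(ordered)}
    lib_rows = []
    for i, c in enumerate(ordered):
        lri_lit = c.lri_true - ((i * 37) % 9 - 4)  # deterministic ±4 offset
        tier = "MRS" if c.quant == "own" else ("MR" if c.quant else "M")
        lib_rows.append(
            {
                "name": c.name,
                "cas": f"0000-{i:02d}-{i % 10}",
                "formula": "",
                "lri_lit": lri_lit,
                "compound_class": c.compound_class,
                "id_tier": tier,
            }
        )
    for j, (name, lri, _level) in enumerate(UBIQUITOUS):
        lib_rows.append(
            {
                "name": name,
                "cas": f"9999-{j:02d}-0",
                "formula": "",
                "lri_lit": lri - 2.0,
                "compound_class": "aromatic_HC" if name != "methyl acetate" else "ester",
                "id_tier": "M",
            }
        )
    library = pd.DataFrame(lib_rows)
    alkanes = pd.DataFrame(
        [{"carbon_number": n, "rt_min": t} for n, t in ladder.entries]
    )

    calib_rows = []
    for c in ordered:
        if c.quant != "own":
            continue
        n_levels = 4 + (sum(map(ord, c.name)) % 5)  # 4–8 levels, deterministic
        masses = np.geomspace(1.0, 100.0, n_levels)
        for m in masses:
            calib_rows.append(
                {
                    "compound": c.name,
                    "mass_ng": float(m),
                    "area": c.calibration_slope * float(m) + c.calibration_intercept,
                }
            )
    calibration = pd.DataFrame(calib_rows)
    surrogates = pd.DataFrame(
        [
            {"compound": c.name, "surrogate": c.quant}
            for c in ordered
            if c.quant not in ("", "own")
        ]
    )

    # --- observations ------------------------------------------------------
    peak_rows = []
    trunk = design[~design["is_background"]]
    for c in ordered:
        fid = feature_of[c.name]
        curve = _quant_curve(c, by_name)
        for row in trunk.itertuples(index=False):
            phase = assign_phase(int(row.day), cfg.phases)
            mult = (
                c.stress_multiplier
                if (row.tree_id != roles.control and phase >= 2)
                else 1.0
            )
            mean = c.baseline.get(row.tree_id, 0.0) * mult
            for kern in c.kernels.get(row.tree_id, []):
                mean += eval_extreme(kern, float(row.day))
            if mean <= 0:
                continue
            rate = mean * _noise_factor(rng, cfg.noise_cv)
            if rate < cfg.detection_threshold:
                continue  # censored: absent row, never a zero
            amount = rate * row.bark_area_dm2 * row.duration_h
            if curve is None:
                area = amount * 1e6  # stays in 1e6-count rate units
            else:
                slope, intercept = curve
                area = slope * amount + intercept
            rt = rt_from_lri(c.lri_true, ladder) + rng.normal(0.0, 0.003)
            peak_rows.append(
                {
                    "sample_id": row.sample_id,
                    "feature_id": fid,
                    "rt_min": round(float(rt), 4),
                    "area": float(area),
                    "match_score": round(float(rng.uniform(80, 99)), 1),
                }
            )
    # ubiquitous ambient features in trunk AND background samples
    n_planted = len(ordered)
    for j, (name, lri, level) in enumerate(UBIQUITOUS):
        fid = f"F{n_planted + j + 1:03d}"
        rt0 = rt_from_lri(lri, ladder)
        for row in design.itertuples(index=False):
            loc_scale = 1.0 if row.location == "outside" else 1.3
            rate = level * loc_scale * _noise_factor(rng, cfg.noise_cv)
            area = rate * 1e6 * cfg.bark_area_dm2 * cfg.duration_h
            peak_rows.append(
                {
                    "sample_id": row.sample_id,
                    "feature_id": fid,
                    "rt_min": round(rt0 + rng.normal(0.0, 0.003), 4),
                    "area": float(area),
                    "match_score": round(float(rng.uniform(80, 99)), 1),
                }
            )
    peaks = pd.DataFrame(peak_rows)

    return {
        "design": design,
        "peaks": peaks,
        "alkanes": alkanes,
        "library": library,
        "calibration": calibration,
        "surrogates": surrogates,
        "truth": truth_table(cfg),
    }


def truth_table(cfg: GeneratorConfig) -> pd.DataFrame:
    """One row per planted compound: the true label and key parameters.

    Consumed only by tests and recovery scoring — it is not part of the
    pipeline's input manifest.
    """
    rows = []
    for c in sorted(cfg.compounds, key=lambda c: c.lri_true):
        rows.append(
            {
                "compound": c.name,
                "true_label": c.true_label,
                "compound_class": c.compound_class,
                "de_novo": c.de_novo,
                "lri_true": c.lri_true,
                "stress_multiplier": c.stress_multiplier,
                "quant": c.quant,
                "n_kernels": sum(len(k) for k in c.kernels.values()),
            }
        )
    return pd.DataFrame(rows)


def write_study(cfg: GeneratorConfig, out_dir) -> dict[str, Path]:
    """Write all generated tables as CSV; returns the path of each table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = generate_study(cfg)
    paths = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
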