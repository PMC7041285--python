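"""Leave-one-out allograft-selection validation.

For every meniscus of the validation group (the bilateral patients),
both same-side menisci of that patient are removed from the pool, then:

1. the gold standard selects the pool meniscus with the closest MeSD to
   the *original* meniscus (the best possible allograft);
2. 3D-MRI sizing selects by closest MeSD to the mirrored contralateral;
3. 2D-MRI sizing selects by width/length error sum of squares against
   the contralateral's 2D measurement;
4. 2D-RX sizing does the same with Pollard-derived dimensions from the
   ipsilateral radiograph.

Each selected meniscus is compared with the original by surface
distance and absolute width/length/height differences; outliers are
width or length difference > 5 mm, height difference > 4 mm, or
MaSD > 5 mm (strict inequalities).

All pairwise surface distances within a side are computed once (the
dominant cost) and reused across cases, keyed by unordered pair.
"""
from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
import yaml

from .bank import AllograftBank, BankEntry
from .mesh_model import Laterality, Side
from .sizing import (
    SelectionResult,
    SizingMethod,
    pollard_derive,
    select_by_dims,
    select_by_mesd,
)
from .stats import pearson_r2, t_test_independent
from .surface_distance import SurfaceDistanceEngine
from .synthetic import PopulationParams

__all__ = [
    "ValidationConfig",
    "CaseComparison",
    "ValidationSummary",
    "PairwiseDistances",
    "compute_pairwise",
    "validation_plan",
    "run_validation",
    "diversity_stats",
    "count_outliers",
    "outlier_flags",
    "OUTLIER_LIMITS_MM",
]

#: strict outlier thresholds (mm): width, length, height diffs and MaSD
OUTLIER_LIMITS_MM = {"width": 5.0, "length": 5.0, "height": 4.0, "masd": 5.0}

_DEFAULT_METHODS = (
    SizingMethod.BEST,
    SizingMethod.MRI3D,
    SizingMethod.MRI2D,
    SizingMethod.RX2D,
)
_METRICS = ("mesd", "masd", "width_diff", "length_diff", "height_diff")


@dataclasses.dataclass
class ValidationConfig:
    """Simulation configuration for the `validate` pipeline."""

    seed: int = 0
    n_bilateral: int = 50
    n_unilateral: int = 40
    density: float = 1.0  # surface-sampling density, points per mm^2
    methods: tuple = _DEFAULT_METHODS
    use_bank_dims2d: bool = False  # score 2D targets against bank dims2d
    population: PopulationParams = dataclasses.field(default_factory=PopulationParams)

    @classmethod
    def from_yaml(cls, path) -> "ValidationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "population" in raw:
            pop = raw["population"]
            from .synthetic import SidePopulation

            for key in ("medial", "lateral"):
                if key in pop:
                    pop[key] = SidePopulation(**pop[key])
            raw["population"] = PopulationParams(**pop)
        if "methods" in raw:
            raw["methods"] = tuple(SizingMethod(m) for m in raw["methods"])
        return cls(**raw)


@dataclasses.dataclass
class CaseComparison:
    """One validation case: selected vs original meniscus."""

    original_id: str
    side: Side
    method: SizingMethod
    selected_id: str
    mesd: float
    masd: float
    width_diff: float
    length_diff: float
    height_diff: float
    outlier_wlh: bool
    outlier_masd: bool


@dataclasses.dataclass
class ValidationSummary:
    """Per side x method summary table, p-value blocks, outlier counts."""

    table: pd.DataFrame  # index (side, method, metric); mean/min/max/sd
    pvalues: pd.DataFrame  # (side, metric, method_a, method_b) -> p
    outliers: pd.DataFrame  # (side, method) -> wlh, masd counts
    counts: dict  # structural counts of the design


class PairwiseDistances:
    """All-pairs MeSD/MaSD among one side's bank entries."""

    def __init__(self, entries: list[BankEntry], engine: SurfaceDistanceEngine):
        self.ids = [e.entry_id for e in entries]
        self.index = {eid: i for i, eid in enumerate(self.ids)}
        n = len(entries)
        self.mesd = np.zeros((n, n))
        self.masd = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            res = engine.distance(entries[i].mesh, entries[j].mesh)
            self.mesd[i, j] = self.mesd[j, i] = res.mesd
            self.masd[i, j] = self.masd[j, i] = res.masd

    def get(self, id_a: str, id_b: str) -> tuple[float, float]:
        i, j = self.index[id_a], self.index[id_b]
        return float(self.mesd[i, j]), float(self.masd[i, j])


def compute_pairwise(
    bank: AllograftBank,
    side: Side | str,
    engine: SurfaceDistanceEngine | None = None,
    density: float = 1.0,
) -> PairwiseDistances:
    engine = engine or SurfaceDistanceEngine(density=density)
    return PairwiseDistances(bank.per_side(side), engine)


def validation_plan(bank: AllograftBank) -> dict:
    """Structural (dry-run) counts of the validation design: bank size,
    per-case pool size, gold-standard evaluations, and diversity pairs,
    per side - no distances are computed."""
    plan = {}
    total_ordered = 0
    for side in (Side.MEDIAL, Side.LATERAL):
        entries = bank.per_side(side)
        n = len(entries)
        validation = bank.validation_ids(side)
        pool_sizes = set()
        for vid in validation:
            entry = bank[vid]
            pool_sizes.add(len(bank.pool(side, exclude_patient=entry.patient_id)))
        ordered_pairs = n * (n - 1)
        total_ordered += ordered_pairs
        plan[side.value] = {
            "bank_size": n,
            "n_validation": len(validation),
            "pool_sizes": sorted(pool_sizes),
            "gold_evaluations": sum(
                len(bank.pool(side, exclude_patient=bank[vid].patient_id))
                for vid in validation
            ),
            "diversity_ordered_pairs": ordered_pairs,
        }
    plan["diversity_ordered_pairs_total"] = total_ordered
    return plan


def outlier_flags(width_diff: float, length_diff: float, height_diff: float,
                  masd: float) -> tuple[bool, bool]:
    """(W/L/H outlier, MaSD outlier) under the strict > thresholds."""
    lim = OUTLIER_LIMITS_MM
    wlh = (width_diff > lim["width"] or length_diff > lim["length"]
           or height_diff > lim["height"])
    return wlh, masd > lim["masd"]


def _compare(bank: AllograftBank, original: BankEntry, method: SizingMethod,
             selection: SelectionResult, pairwise: PairwiseDistances) -> CaseComparison:
    selected = bank[selection.selected_id]
    mesd, masd = pairwise.get(original.entry_id, selected.entry_id)
    wd = abs(original.dims3d.width - selected.dims3d.width)
    ld = abs(original.dims3d.length - selected.dims3d.length)
    hd = abs(original.dims3d.height - selected.dims3d.height)
    wlh, masd_out = outlier_flags(wd, ld, hd, masd)
    return CaseComparison(
        original_id=original.entry_id,
        side=original.side,
        method=method,
        selected_id=selected.entry_id,
        mesd=mesd,
        masd=masd,
        width_diff=wd,
        length_diff=ld,
        height_diff=hd,
        outlier_wlh=wlh,
        outlier_masd=masd_out,
    )


def run_validation(
    bank: AllograftBank,
    config: ValidationConfig | None = None,
    pairwise: dict[str, PairwiseDistances] | None = None,
    engine: SurfaceDistanceEngine | None = None,
) -> tuple[list[CaseComparison], ValidationSummary]:
    """Run the leave-one-out selection simulation over both sides.

    ``pairwise`` may carry precomputed per-side distance matrices (keys
    'medial'/'lateral'); otherwise they are computed here with
    ``engine`` (or a fresh engine at the configured density).
    """
    config = config or ValidationConfig()
    engine = engine or SurfaceDistanceEngine(density=config.density)
    pairwise = dict(pairwise or {})
    comparisons: list[CaseComparison] = []
    counts = validation_plan(bank)

    for side in (Side.MEDIAL, Side.LATERAL):
        if side.value not in pairwise:
            pairwise[side.value] = PairwiseDistances(bank.per_side(side), engine)
        pw = pairwise[side.value]

        for vid in bank.validation_ids(side):
            original = bank[vid]
            pid = original.patient_id
            contra = bank.contralateral(original)
            for method in config.methods:
                method = SizingMethod(method)
                if method in (SizingMethod.BEST, SizingMethod.MRI3D):
                    template_entry = original if method is SizingMethod.BEST else contra
                    if template_entry is None:
                        raise ValueError(
                            f"{vid}: contralateral partner missing for {method.value}"
                        )
                    tid = template_entry.entry_id
                    selection = select_by_mesd(
                        template_entry.mesh, bank, side,
                        exclude_patient=pid, method=method,
                        mesd_lookup=lambda tmpl, e, tid=tid: pw.get(tid, e.entry_id)[0],
                    )
                elif method is SizingMethod.MRI2D:
                    if contra is None:
                        raise ValueError(f"{vid}: contralateral partner missing for mri2d")
                    selection = select_by_dims(
                        contra.dims2d, bank, side, exclude_patient=pid,
                        method=method, use_bank_dims2d=config.use_bank_dims2d,
                    )
                elif method is SizingMethod.RX2D:
                    rx = bank.radiograph(pid, original.source_laterality, side)
                    target = pollard_derive(rx, side)
                    selection = select_by_dims(
                        target, bank, side, exclude_patient=pid,
                        method=method, use_bank_dims2d=config.use_bank_dims2d,
                    )
                else:
                    raise ValueError(f"unknown method {method}")
                comparisons.append(_compare(bank, original, method, selection, pw))

    summary = summarize(comparisons, counts, methods=tuple(
        SizingMethod(m) for m in config.methods))
    return comparisons, summary


def comparisons_frame(comparisons: list[CaseComparison]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(c) for c in comparisons])
    df["side"] = df["side"].map(lambda s: Side(s).value)
    df["method"] = df["method"].map(lambda m: SizingMethod(m).value)
    return df


def count_outliers(comparisons: list[CaseComparison]) -> pd.DataFrame:
    """W/L/H- and MaSD-outlier counts per (side, method)."""
    df = comparisons_frame(comparisons)
    grouped = df.groupby(["side", "method"])[["outlier_wlh", "outlier_masd"]].sum()
    grouped.columns = ["wlh_outliers", "masd_outliers"]
    grouped["cases"] = df.groupby(["side", "method"]).size()
    return grouped.astype(int)


def summarize(comparisons: list[CaseComparison], counts: dict,
              methods: tuple = _DEFAULT_METHODS) -> ValidationSummary:
    df = comparisons_frame(comparisons)
    method_names = [SizingMethod(m).value for m in methods]

    rows = []
    for (side, method), grp in df.groupby(["side", "method"]):
        for metric in _METRICS:
            vals = grp[metric].to_numpy()
            rows.append({
                "side": side, "method": method, "metric": metric,
                "mean": vals.mean(), "min": vals.min(),
                "max": vals.max(), "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
            })
    table = pd.DataFrame(rows).set_index(["side", "method", "metric"]).sort_index()

    # pairwise Welch t tests per metric, Bonferroni over the method pairs
    n_pairs = len(method_names) * (len(method_names) - 1) // 2
    prows = []
    for side, sgrp in df.groupby("side"):
        by_method = {m: g for m, g in sgrp.groupby("method")}
        for metric in _METRICS:
            for ma, mb in itertools.combinations(method_names, 2):
                if ma not in by_method or mb not in by_method:
                    continue
                x = by_method[ma][metric].to_numpy()
                y = by_method[mb][metric].to_numpy()
                try:
                    p = t_test_independent(x, y, n_comparisons=max(n_pairs, 1))
                except ValueError:
                    p = np.nan
                prows.append({"side": side, "metric": metric,
                              "method_a": ma, "method_b": mb, "p": p})
    pvalues = pd.DataFrame(prows)
    if len(pvalues):
        pvalues = pvalues.set_index(["side", "metric", "method_a", "method_b"])

    return ValidationSummary(
        table=table,
        pvalues=pvalues,
        outliers=count_outliers(comparisons),
        counts=counts,
    )


def diversity_stats(
    bank: AllograftBank,
    pairwise: dict[str, PairwiseDistances] | None = None,
    engine: SurfaceDistanceEngine | None = None,
    density: float = 1.0,
) -> pd.DataFrame:
    """All-ordered-pairs MeSD/MaSD diversity of the bank, per side.

    Reports n(n-1) ordered pairs per side with mean/SD/min/max of MeSD
    and MaSD, plus Pearson R^2 of width vs length and MeSD vs MaSD.
    """
    engine = engine or SurfaceDistanceEngine(density=density)
    pairwise = dict(pairwise or {})
    rows = []
    for side in (Side.MEDIAL, Side.LATERAL):
        entries = bank.per_side(side)
        if len(entries) < 2:
            raise ValueError("need >= 2 entries per side")
        if side.value not in pairwise:
            pairwise[side.value] = PairwiseDistances(entries, engine)
        pw = pairwise[side.value]
        n = len(entries)
        mask = ~np.eye(n, dtype=bool)
        mesd = pw.mesd[mask]  # ordered pairs: each unordered pair twice
        masd = pw.masd[mask]
        widths = np.array([e.dims3d.width for e in entries])
        lengths = np.array([e.dims3d.length for e in entries])
        rows.append({
            "side": side.value,
            "n_entries": n,
            "n_pairs": int(mask.sum()),
            "mesd_mean": mesd.mean(), "mesd_sd": mesd.std(ddof=1),
            "mesd_min": mesd.min(), "mesd_max": mesd.max(),
            "masd_mean": masd.mean(), "masd_sd": masd.std(ddof=1),
            "masd_min": masd.min(), "masd_max": masd.max(),
            "r2_width_length": (pearson_r2(widths, lengths)
                                if n >= 3 else np.nan),
            "r2_mesd_masd": (pearson_r2(mesd, masd)
                             if len(mesd) >= 3 and np.ptp(mesd) > 0 else np.nan),
        })
    return pd.DataFrame(rows).set_index("side")
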