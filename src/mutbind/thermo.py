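"""Binding thermodynamics: Kd <-> ddG, additivity and replicate statistics.

The free-energy change of binding caused by a mutation follows from the
equilibrium dissociation constants of mutant and wild type,

    ddG = -R T ln(Kd_wt / Kd_mut),

so a mutant that binds tighter (smaller Kd) has negative ddG. Kd itself
decomposes kinetically as Kd = kd/ka. Replicate scatter is summarized by the
estimated standard deviation (esd) and Student-t confidence half-widths
t_{(1+level)/2, n-1} * esd / sqrt(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "R_GAS",
    "T_STANDARD",
    "AffinityMeasurement",
    "DdgExperimental",
    "AdditivityRecord",
    "ddg_from_kd",
    "kd_from_rates",
    "fold_change",
    "t_confidence_halfwidth",
    "additivity_table",
    "read_affinity_csv",
    "write_affinity_csv",
    "affinity_report",
]

R_GAS = 8.314        # J/(mol K)
T_STANDARD = 298.15  # K; SPR affinities measured at 25 C


@dataclass
class AffinityMeasurement:
    """One row of an SPR affinity table: rates, Kd and replicate scatter.

    Units are SI: ka in 1/(M s), kd_rate in 1/s, Kd and esd in M. esd is
    reported only for variants measured in >= 3 replicates.
    """

    variant: str
    ka: float
    kd_rate: float
    Kd: float
    n_replicates: int
    esd: float | None = None
    batch: str | None = None

    def __post_init__(self) -> None:
        for name in ("ka", "kd_rate", "Kd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.variant}: {name} must be positive")
        if self.esd is not None and self.n_replicates < 3:
            raise ValueError(
                f"{self.variant}: esd given but only {self.n_replicates} replicates (need >= 3)"
            )


@dataclass
class DdgExperimental:
    variant: str
    ddg: float                 # kJ/mol
    esd: float | None = None   # kJ/mol
    temperature: float = T_STANDARD

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not math.isfinite(self.ddg):
            raise ValueError("ddg must be finite")


@dataclass
class AdditivityRecord:
    multi: str
    sum_of_singles: float
    measured: float

    @property
    def deviation(self) -> float:
        return self.measured - self.sum_of_singles


def ddg_from_kd(kd_mut: float, kd_wt: float, temperature: float = T_STANDARD) -> float:
    """ddG = -R T ln(Kd_wt / Kd_mut) in kJ/mol; negative = mutant binds tighter."""
    if kd_mut <= 0 or kd_wt <= 0 or temperature <= 0:
        raise ValueError("Kd values and temperature must be positive")
    return -R_GAS * temperature * math.log(kd_wt / kd_mut) / 1000.0


def kd_from_rates(ka: float, kd_rate: float) -> float:
    """Kd = kd/ka (M)."""
    if ka <= 0 or kd_rate <= 0:
        raise ValueError("rate constants must be positive")
    return kd_rate / ka


def fold_change(kd_wt: float, kd_mut: float) -> float:
    """Kd_wt / Kd_mut; > 1 means the mutant binds tighter than wild type."""
    if kd_wt <= 0 or kd_mut <= 0:
        raise ValueError("Kd values must be positive")
    return kd_wt / kd_mut


def t_confidence_halfwidth(esd: float, n: int, level: float = 0.95) -> float:
    """Student-t confidence half-width for the mean of n replicates."""
    if n < 2:
        raise ValueError("need at least 2 replicates")
    if esd <= 0:
        raise ValueError("esd must be positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    t_crit = stats.t.ppf((1 + level) / 2, df=n - 1)
    return float(t_crit * esd / math.sqrt(n))


def additivity_table(singles, multis) -> list[AdditivityRecord]:
    """Compare each multi-mutant's measured ddG with the sum of its singles.

    ``singles`` is an iterable of DdgExperimental for single mutants;
    ``multis`` pairs a multi-mutant label (constituents joined by '+' or ';')
    with its DdgExperimental. A missing constituent is an error.
    """
    by_variant = {s.variant: s for s in singles}
    records = []
    for label, measured in multis:
        parts = [p.strip() for p in label.replace("+", ";").split(";") if p.strip()]
        try:
            total = sum(by_variant[p].ddg for p in parts)
        except KeyError as err:
            raise ValueError(f"{label}: missing single-mutant measurement {err}") from None
        records.append(
            AdditivityRecord(multi=label, sum_of_singles=total, measured=measured.ddg)
        )
    return records


# ---------------------------------------------------------------------------
# Affinity-table I/O and the aggregate report


CSV_COLUMNS = ["variant", "ka_per_M_s", "kd_per_s", "Kd_M", "n_replicates", "esd_M"]


def read_affinity_csv(path) -> list[AffinityMeasurement]:
    """Read an affinity table CSV: variant, ka_per_M_s, kd_per_s, Kd_M,
    n_replicates, esd_M (empty esd for < 3 replicates); optional batch."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        esd = getattr(row, "esd_M")
        esd = None if pd.isna(esd) else float(esd)
        out.append(
            AffinityMeasurement(
                variant=str(row.variant),
                ka=float(row.ka_per_M_s),
                kd_rate=float(row.kd_per_s),
                Kd=float(row.Kd_M),
                n_replicates=int(row.n_replicates),
                esd=esd,
                batch=str(row.batch) if "batch" in df.columns and not pd.isna(row.batch) else None,
            )
        )
    return out


def write_affinity_csv(measurements, path) -> None:
    recs = [
        {
            "variant": m.variant,
            "ka_per_M_s": m.ka,
            "kd_per_s": m.kd_rate,
            "Kd_M": m.Kd,
            "n_replicates": m.n_replicates,
            "esd_M": m.esd if m.esd is not None else "",
        }
        for m in measurements
    ]
    pd.DataFrame(recs).to_csv(path, index=False)


def affinity_report(
    measurements,
    wt_label: str = "WT",
    temperature: float = T_STANDARD,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-variant ddG vs wild type, fold change and CI half-width.

    Variants whose label contains '+' or ';' are treated as multi-mutants
    and additivity deviations are computed when all constituent singles are
    present. Cross-batch comparisons (variant batch differing from the WT
    row's batch) are flagged rather than suppressed.
    """
    by_variant = {m.variant: m for m in measurements}
    if wt_label not in by_variant:
        raise ValueError(f"wild-type row {wt_label!r} missing from affinity table")
    wt = by_variant[wt_label]

    singles: dict[str, float] = {}
    rows = []
    for m in measurements:
        ddg = 0.0 if m.variant == wt_label else ddg_from_kd(m.Kd, wt.Kd, temperature)
        halfwidth = (
            t_confidence_halfwidth(m.esd, m.n_replicates, level) if m.esd is not None else None
        )
        cross_batch = (
            m.batch is not None and wt.batch is not None and m.batch != wt.batch
        )
        is_multi = ("+" in m.variant) or (";" in m.variant)
        if not is_multi and m.variant != wt_label:
            singles[m.variant] = ddg
        rows.append(
            {
                "variant": m.variant,
                "Kd_nM": m.Kd * 1e9,
                "ddG_kJ_mol": ddg,
                "fold_change": fold_change(wt.Kd, m.Kd),
                "n_replicates": m.n_replicates,
                "esd_nM": m.esd * 1e9 if m.esd is not None else float("nan"),
                "ci95_halfwidth_nM": halfwidth * 1e9 if halfwidth is not None else float("nan"),
                "cross_batch": cross_batch,
            }
        )

    df = pd.DataFrame(rows)
    sums, devs = [], []
    for row in rows:
        variant = row["variant"]
        if ("+" in variant or ";" in variant):
            parts = [p.strip() for p in variant.replace("+", ";").split(";")]
            if all(p in singles for p in parts):
                total = sum(singles[p] for p in parts)
                sums.append(total)
                devs.append(row["ddG_kJ_mol"] - total)
                continue
        sums.append(float("nan"))
        devs.append(float("nan"))
    df["sum_of_singles_kJ_mol"] = sums
    df["additivity_deviation_kJ_mol"] = devs
    return df
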