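"""TOD-DHS: titration-of-digestion quality control for DNase-seq samples.

A DNase concentration series is run over benchmark loci that are either
hypersensitive ("sensitive") or closed ("resistant") in essentially all cell
types, and each aliquot is assayed by qPCR. Because qPCR signal doubles once
per cycle (at ideal efficiency), the surviving — undigested — template
fraction at a site is ``efficiency**(cq_undigested - cq_digested)``, so

    fraction_digested = 1 - efficiency**(cq0 - cq)

with the undigested (0 U) aliquot as the reference. The sample digested to
70–80% at the sensitive benchmark sites, with no digestion at resistant
sites, is selected as the biological replicate to sequence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WINDOW = (0.70, 0.80)

REQUIRED_COLUMNS = ("site_id", "site_class", "dnase_units", "replicate", "cq")


@dataclass
class TitrationCurve:
    """Fraction digested versus DNase concentration at one benchmark site."""

    site_id: str
    site_class: str  # "sensitive" or "resistant"
    points: list[tuple[float, float, float]]  # (dnase_units, fraction, sd)
    flags: list[str] = field(default_factory=list)


@dataclass
class ReplicaSelection:
    selected_units: float | None
    window: tuple[float, float]
    resistant_max: float
    mean_sensitive: dict[float, float]
    mean_resistant: dict[float, float]
    flags: list[str] = field(default_factory=list)


def fraction_digested(
    cq_undigested: float,
    cq_digested: float,
    efficiency: float = 2.0,
) -> tuple[float, list[str]]:
    """Digested fraction from a Cq pair, clamped to [0, 1].

    ``cq_digested`` of NaN encodes "no amplification" (the template was
    digested to completion) and maps to 1.0 with a flag. A Cq *smaller* than
    the undigested control would imply a negative digested fraction; it is
    clamped to 0 and flagged.

    Returns ``(fraction, flags)``.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    if math.isnan(cq_undigested):
        raise ValueError("undigested Cq must be finite")
    flags: list[str] = []
    if math.isnan(cq_digested):
        return 1.0, ["no amplification"]
    frac = 1.0 - efficiency ** (cq_undigested - cq_digested)
    if frac < 0.0:
        flags.append("negative delta-Cq")
        frac = 0.0
    elif frac > 1.0:  # unreachable for efficiency > 1, kept as a guard
        frac = 1.0
    return frac, flags


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"titration table missing columns: {missing}")
    finite = table["cq"].dropna()
    if (finite <= 0).any():
        raise ValueError("Cq values must be positive")


def titration_curves(
    table: pd.DataFrame, efficiency: float = 2.0
) -> list[TitrationCurve]:
    """One digestion curve per benchmark site.

    Replicate Cq values are averaged before the exponential transform (the
    transform of the mean); the per-point sd is the spread of per-replicate
    fractions, each transformed against the mean undigested Cq — a numerical
    propagation of the Cq spread through the nonlinearity.
    """
    _validate_table(table)
    curves = []
    for site_id, grp in table.groupby("site_id", sort=True):
        classes = grp["site_class"].unique()
        if len(classes) != 1:
            raise ValueError(f"site {site_id} has conflicting site_class values")
        zero = grp[grp["dnase_units"] == 0]
        if zero.empty:
            raise ValueError(f"site {site_id} has no undigested (0 U) row")
        cq0 = float(zero["cq"].mean())
        points = []
        flags: list[str] = []
        for units, sub in grp[grp["dnase_units"] > 0].groupby("dnase_units", sort=True):
            cqs = sub["cq"]
            if cqs.isna().all():
                points.append((float(units), 1.0, 0.0))
                flags.append(f"no amplification at {units} U")
                continue
            frac, fl = fraction_digested(cq0, float(cqs.mean()), efficiency)
            flags.extend(f"{f} at {units} U" for f in fl)
            per_rep = np.array(
                [fraction_digested(cq0, c, efficiency)[0] for c in cqs.dropna()]
            )
            sd = float(per_rep.std(ddof=1)) if per_rep.size > 1 else 0.0
            points.append((float(units), frac, sd))
        curves.append(
            TitrationCurve(
                site_id=str(site_id),
                site_class=str(classes[0]),
                points=points,
                flags=flags,
            )
        )
    return curves


def select_replica(
    curves: list[TitrationCurve],
    window: tuple[float, float] = DEFAULT_WINDOW,
    resistant_max: float = 0.10,
) -> ReplicaSelection:
    """Pick the gentlest DNase concentration inside the digestion window.

    A concentration qualifies when the mean fraction digested over sensitive
    sites lies in ``window`` and the mean over resistant sites stays at or
    below ``resistant_max``; among qualifying concentrations the smallest
    (least digestion) wins. With no qualifier, ``selected_units`` is None
    and a flag explains why.
    """
    if not curves:
        raise ValueError("no titration curves given")
    sens = [c for c in curves if c.site_class == "sensitive"]
    if not sens:
        raise ValueError("need at least one sensitive-site curve")
    resist = [c for c in curves if c.site_class == "resistant"]

    def mean_by_units(cs: list[TitrationCurve]) -> dict[float, float]:
        acc: dict[float, list[float]] = {}
        for c in cs:
            for units, frac, _sd in c.points:
                acc.setdefault(units, []).append(frac)
        return {u: float(np.mean(v)) for u, v in acc.items()}

    mean_sens = mean_by_units(sens)
    mean_res = mean_by_units(resist)
    lo, hi = window
    flags: list[str] = []
    selected = None
    for units in sorted(mean_sens):
        if not lo <= mean_sens[units] <= hi:
            continue
        if mean_res.get(units, 0.0) > resistant_max:
            flags.append(f"{units} U rejected: resistant sites digested")
            continue
        selected = units
        break
    if selected is None:
        flags.append("no concentration in window")
    return ReplicaSelection(
        selected_units=selected,
        window=window,
        resistant_max=resistant_max,
        mean_sensitive=mean_sens,
        mean_resistant=mean_res,
        flags=flags,
    )
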