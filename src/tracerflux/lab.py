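"""Sealed-jar headspace fluxes and three-pool partitioning.

The lab experiment incubates each soil sample under three treatments:

* **control** — soil alone; its CO2 is pure soil-organic-carbon (SOC)
  respiration and provides the soil end member for mixing,
* **unlabeled** — soil + C4 litter + natural-abundance lignin,
* **labeled** — soil + C4 litter + lignin carrying 99 atom% 13C at the
  Cbeta position of each C9 unit.

Jars stay sealed between headspace samplings and are flushed with CO2-free
air afterwards, so each measured concentration is the CO2 produced since the
previous flush; interval fluxes are therefore the primitive observations and
cumulative series are their sums.  Partitioning happens per interval in atom
fraction space:

* litter vs soil in the unlabeled jar against the paired control,
  ``f_litter = (F_t2 - F_control) / (F_litter - F_control)``,
* the Cbeta tracer in the labeled jar against the paired unlabeled jar,
  ``cbeta_c = total_t3 * (F_t3 - F_t2) / (F_label - F_t2)``.

Fractions are never clipped; QC conditions become row flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import PairingError, SchemaError
from .isotopes import (
    DEFAULT_MIN_SEPARATION,
    atom_fraction_to_delta,
    delta_to_atom_fraction,
    two_source_fraction,
)

#: Ideal gas constant, J mol-1 K-1.
R_GAS = 8.31446
#: Molar mass of carbon, g mol-1.
MOLAR_MASS_C = 12.011
#: Standard pressure assumed in every jar, Pa.
STANDARD_PRESSURE_PA = 101_325.0
#: Operating ceiling for headspace CO2; exceeding it is flagged.
CO2_CEILING_PPM = 5000.0
#: Initial O2 mole percent of the flush gas.
INITIAL_O2_PCT = 20.9
#: O2 drawdown (% of initial O2) above which an interval is flagged.
O2_DRAWDOWN_LIMIT_PCT = 2.4

HEADSPACE_COLUMNS = (
    "jar_id",
    "day",
    "co2_ppm",
    "delta_co2_permil",
    "jar_volume_ml",
    "temperature_k",
)

POOLS = ("soc", "litter", "lignin_cbeta")


def co2_c_mass_ug(ppm, volume_ml, temperature_k, pressure_pa=STANDARD_PRESSURE_PA):
    """CO2-C mass (ug) in a headspace of given volume at a CO2 mole fraction.

    mass = ppm * 1e-6 * (P V / (R T)) * 12.011e6, with V in m3.
    Linear in ppm; 0 ppm -> 0 ug.
    """
    ppm = np.asarray(ppm, dtype=float)
    if np.any(ppm[~np.isnan(ppm)] < 0):
        raise SchemaError("co2_ppm must be >= 0", column="co2_ppm")
    n_total = pressure_pa * (np.asarray(volume_ml, float) * 1e-6) / (
        R_GAS * np.asarray(temperature_k, float)
    )
    mass = ppm * 1e-6 * n_total * MOLAR_MASS_C * 1e6
    return float(mass) if mass.ndim == 0 else mass


def ppm_from_co2_c_ug(mass_ug, volume_ml, temperature_k,
                      pressure_pa=STANDARD_PRESSURE_PA):
    """Inverse of :func:`co2_c_mass_ug` (used by the simulator)."""
    n_total = pressure_pa * (np.asarray(volume_ml, float) * 1e-6) / (
        R_GAS * np.asarray(temperature_k, float)
    )
    ppm = np.asarray(mass_ug, float) / (n_total * MOLAR_MASS_C * 1e6) * 1e6
    return float(ppm) if ppm.ndim == 0 else ppm


def o2_drawdown_pct(co2_ppm, initial_o2_pct=INITIAL_O2_PCT):
    """O2 consumed during a sealed interval, as % of the initial O2 supply.

    Assumes 1:1 CO2-production : O2-consumption stoichiometry, so the O2 loss
    in mole-percent equals the CO2 mole-percent (ppm / 1e4).
    """
    if not initial_o2_pct > 0:
        raise SchemaError("initial_o2_pct must be > 0")
    co2_pct = np.asarray(co2_ppm, dtype=float) / 1e4
    out = 100.0 * co2_pct / initial_o2_pct
    return float(out) if out.ndim == 0 else out


def _require_columns(df: pd.DataFrame, cols, path=None):
    for c in cols:
        if c not in df.columns:
            raise SchemaError("missing required column", path=path, column=c)


def interval_fluxes(headspace: pd.DataFrame, pressure_pa=STANDARD_PRESSURE_PA,
                    path=None) -> pd.DataFrame:
    """Convert a headspace time series into per-interval CO2-C fluxes.

    Each measurement at ``day`` covers the half-open interval
    ``(previous day, day]`` with day 0 = incubation start.  Returns one row
    per jar x interval with columns ``co2_c_ug``, ``atom_fraction``, O2
    drawdown and QC flags.
    """
    _require_columns(headspace, HEADSPACE_COLUMNS, path=path)
    hs = headspace.copy()
    bad = hs.index[hs["co2_ppm"] < 0]
    if len(bad):
        raise SchemaError("negative co2_ppm", path=path, column="co2_ppm",
                          row=int(bad[0]) + 1)
    hs = hs.sort_values(["jar_id", "day"], kind="mergesort")
    for jar, grp in hs.groupby("jar_id", sort=False):
        d = grp["day"].to_numpy()
        if np.any(np.diff(d) <= 0) or np.any(d <= 0):
            raise SchemaError("days must be strictly increasing and > 0",
                              path=path, column="day")

    hs["day_start"] = hs.groupby("jar_id")["day"].shift(1).fillna(0.0)
    hs = hs.rename(columns={"day": "day_end"})
    hs["co2_c_ug"] = co2_c_mass_ug(
        hs["co2_ppm"].to_numpy(), hs["jar_volume_ml"].to_numpy(),
        hs["temperature_k"].to_numpy(), pressure_pa)
    hs["atom_fraction"] = delta_to_atom_fraction(hs["delta_co2_permil"].to_numpy())
    hs["o2_drawdown_pct"] = o2_drawdown_pct(hs["co2_ppm"].to_numpy())

    flags = []
    for ppm, o2 in zip(hs["co2_ppm"], hs["o2_drawdown_pct"]):
        row = []
        if ppm > CO2_CEILING_PPM:
            row.append("co2_above_ceiling")
        if o2 > O2_DRAWDOWN_LIMIT_PCT:
            row.append("o2_drawdown_exceeded")
        flags.append(";".join(row))
    hs["qc_flags"] = flags
    cols = ["jar_id", "day_start", "day_end", "co2_ppm", "co2_c_ug",
            "delta_co2_permil", "atom_fraction", "o2_drawdown_pct", "qc_flags"]
    return hs[cols].reset_index(drop=True)


def partition_soil_litter(total_c_ug, f_t2, f_control, f_litter,
                          min_separation=DEFAULT_MIN_SEPARATION):
    """Split unlabeled-jar CO2-C between litter and soil sources.

    Returns ``(litter_c, soc_c, f_litter_frac)`` with
    ``litter_c + soc_c == total_c_ug`` exactly (mass balance preserved even
    for out-of-range fractions, which callers flag).
    """
    f = two_source_fraction(f_t2, f_control, f_litter, min_separation)
    litter_c = np.asarray(f) * np.asarray(total_c_ug, float)
    soc_c = np.asarray(total_c_ug, float) - litter_c
    if np.ndim(f) == 0:
        return float(litter_c), float(soc_c), float(f)
    return litter_c, soc_c, f


def partition_cbeta(total_t3_ug, f_t3, f_t2, f_label,
                    min_separation=DEFAULT_MIN_SEPARATION):
    """CO2-C attributed to the 13Cbeta tracer in the labeled jar.

    cbeta = total_t3 * (F_t3 - F_t2) / (F_label - F_t2); the paired unlabeled
    jar supplies the background composition.  Negative values (F_t3 < F_t2)
    are returned as-is for downstream flagging.
    """
    f = two_source_fraction(f_t3, f_t2, f_label, min_separation)
    out = np.asarray(f) * np.asarray(total_t3_ug, float)
    if np.ndim(f) == 0:
        return float(out), float(f)
    return out, f


# fraction window outside which the soil/litter split is flagged
_FRACTION_WINDOW = (-0.05, 1.05)
# tracer fraction below which a negative-tracer flag is raised
_NEGATIVE_TRACER_TOL = -1e-4


def partition_intervals(fluxes: pd.DataFrame, manifest: pd.DataFrame,
                        min_separation=DEFAULT_MIN_SEPARATION,
                        correct_litter_for_cbeta=True) -> pd.DataFrame:
    """Partition every treatment triplet's interval fluxes among the pools.

    Triplets are matched by (site_id, point_id, depth, n_addition); the
    control jar is shared between the ambient and N-addition arms of a
    sampling point.  A missing paired control falls back to the site-mean
    control composition for the interval, with a ``control_imputed`` flag.

    The unlabeled jar's Cbeta pool is chemically identical to the labeled
    jar's, so with ``correct_litter_for_cbeta`` (default) the tracer estimate
    is subtracted from the litter component; ``litter_c_raw`` retains the
    strictly additive soil/litter split (litter_c_raw + soc_c = total).
    """
    _require_columns(manifest, ("jar_id", "site_id", "point_id", "depth",
                                "treatment", "n_addition", "litter_delta_permil",
                                "label_atom_fraction"))
    merged = fluxes.merge(manifest, on="jar_id", how="left", validate="m:1")
    if merged["treatment"].isna().any():
        missing = merged.loc[merged["treatment"].isna(), "jar_id"].iloc[0]
        raise PairingError(f"jar {missing} present in headspace but not manifest")

    key = ["site_id", "point_id", "depth", "n_addition", "day_start", "day_end"]
    ctl_key = ["site_id", "point_id", "depth", "day_start", "day_end"]

    t2 = merged[merged["treatment"] == "unlabeled"]
    t3 = merged[merged["treatment"] == "labeled"]
    ctl = merged[merged["treatment"] == "control"]

    pair = t2.merge(
        t3[key + ["jar_id", "co2_c_ug", "atom_fraction", "cbeta_initial_c_ug"]],
        on=key, how="left", suffixes=("_t2", "_t3"), validate="1:1")
    pair = pair.merge(
        ctl[ctl_key + ["co2_c_ug", "atom_fraction"]].rename(
            columns={"co2_c_ug": "co2_c_ug_ctl", "atom_fraction": "f_ctl"}),
        on=ctl_key, how="left", validate="m:1")

    # site-mean control composition (mass-weighted) per interval, for fallback
    site_ctl = (
        ctl.assign(wf=lambda d: d["co2_c_ug"] * d["atom_fraction"])
        .groupby(["site_id", "day_start", "day_end"])
        .agg(wf=("wf", "sum"), w=("co2_c_ug", "sum"))
        .reset_index()
    )
    site_ctl["f_ctl_site"] = np.where(site_ctl["w"] > 0,
                                      site_ctl["wf"] / site_ctl["w"], np.nan)
    pair = pair.merge(site_ctl[["site_id", "day_start", "day_end", "f_ctl_site"]],
                      on=["site_id", "day_start", "day_end"], how="left")

    imputed = pair["f_ctl"].isna() & pair["f_ctl_site"].notna()
    no_control = pair["f_ctl"].isna() & pair["f_ctl_site"].isna() & (
        pair["co2_c_ug_t2"] > 0)
    if no_control.any():
        bad = pair.loc[no_control].iloc[0]
        raise PairingError(
            f"no paired or site-level control for site={bad['site_id']} "
            f"point={bad['point_id']} depth={bad['depth']}")
    pair["f_ctl"] = pair["f_ctl"].where(~imputed, pair["f_ctl_site"])

    f_litter_em = delta_to_atom_fraction(pair["litter_delta_permil"].to_numpy())
    f_label = pair["label_atom_fraction"].to_numpy()

    tot2 = pair["co2_c_ug_t2"].to_numpy()
    tot3 = pair["co2_c_ug_t3"].to_numpy()
    f_t2 = pair["atom_fraction_t2"].to_numpy()
    f_t3 = pair["atom_fraction_t3"].to_numpy()
    f_ctl_arr = pair["f_ctl"].to_numpy()

    n = len(pair)
    litter_raw = np.zeros(n)
    soc_c = np.zeros(n)
    cbeta_c = np.zeros(n)
    f_lit = np.full(n, np.nan)
    f_cb = np.full(n, np.nan)

    active2 = tot2 > 0
    if active2.any():
        lr, sc, fl = partition_soil_litter(
            tot2[active2], f_t2[active2], f_ctl_arr[active2],
            f_litter_em[active2], min_separation)
        litter_raw[active2], soc_c[active2] = np.atleast_1d(lr), np.atleast_1d(sc)
        f_lit[active2] = np.atleast_1d(fl)
    active3 = tot3 > 0
    if active3.any():
        cb, fc = partition_cbeta(tot3[active3], f_t3[active3], f_t2[active3],
                                 f_label[active3], min_separation)
        cbeta_c[active3] = np.atleast_1d(cb)
        f_cb[active3] = np.atleast_1d(fc)

    litter_c = litter_raw - cbeta_c if correct_litter_for_cbeta else litter_raw

    flags = []
    lo, hi = _FRACTION_WINDOW
    for i in range(n):
        row = []
        if imputed.iloc[i]:
            row.append("control_imputed")
        if np.isfinite(f_lit[i]) and not (lo <= f_lit[i] <= hi):
            row.append("f_litter_out_of_range")
        if np.isfinite(f_cb[i]) and f_cb[i] < _NEGATIVE_TRACER_TOL:
            row.append("negative_tracer")
        flags.append(";".join(row))

    out = pd.DataFrame({
        "site_id": pair["site_id"],
        "point_id": pair["point_id"],
        "depth": pair["depth"],
        "n_addition": pair["n_addition"],
        "day_start": pair["day_start"],
        "day_end": pair["day_end"],
        "total_t2_c_ug": tot2,
        "total_t3_c_ug": tot3,
        "f_litter": f_lit,
        "f_cbeta": f_cb,
        "soc_c_ug": soc_c,
        "litter_c_raw_ug": litter_raw,
        "litter_c_ug": litter_c,
        "cbeta_c_ug": cbeta_c,
        "soc_initial_c_ug": pair["soc_initial_c_ug"],
        "litter_initial_c_ug": pair["litter_initial_c_ug"],
        "cbeta_initial_c_ug": pair["cbeta_initial_c_ug_t2"],
        "qc_flags": flags,
    })
    return out.sort_values(["site_id", "point_id", "depth", "n_addition",
                            "day_end"]).reset_index(drop=True)


DEFAULT_CHECKPOINTS = (183, 365, 571)


def accumulate(partitions: pd.DataFrame,
               checkpoints=DEFAULT_CHECKPOINTS) -> pd.DataFrame:
    """Cumulative pool C and percent-of-initial-pool at checkpoint days.

    A checkpoint sums all intervals with ``day_end <= checkpoint`` and reports
    the effective day actually covered (the last interval boundary), so
    estimates can be compared against ground truth at identical coverage.
    """
    rows = []
    gcols = ["site_id", "point_id", "depth", "n_addition"]
    for keys, grp in partitions.groupby(gcols, sort=False):
        grp = grp.sort_values("day_end")
        if grp["day_start"].iloc[0] != 0:
            cover_flag = "coverage_gap"
        elif np.any(grp["day_start"].to_numpy()[1:]
                    != grp["day_end"].to_numpy()[:-1]):
            cover_flag = "coverage_gap"
        else:
            cover_flag = ""
        for cp in checkpoints:
            sub = grp[grp["day_end"] <= cp]
            if sub.empty:
                continue
            rec = dict(zip(gcols, keys))
            rec["checkpoint_day"] = cp
            rec["effective_day"] = sub["day_end"].max()
            for pool, col, init in (
                ("soc", "soc_c_ug", "soc_initial_c_ug"),
                ("litter", "litter_c_ug", "litter_initial_c_ug"),
                ("lignin_cbeta", "cbeta_c_ug", "cbeta_initial_c_ug"),
            ):
                total = sub[col].sum()
                denom = grp[init].iloc[0]
                rec[f"{pool}_cum_c_ug"] = total
                rec[f"pct_{pool}"] = (
                    100.0 * total / denom if denom and denom > 0 else np.nan)
            sub_flags = [f for f in sub["qc_flags"] if f]
            all_flags = ([cover_flag] if cover_flag else []) + sub_flags
            rec["qc_flags"] = ";".join(sorted(set(
                g for f in all_flags for g in f.split(";") if g)))
            rows.append(rec)
    return pd.DataFrame(rows)


def instantaneous_rates(partitions: pd.DataFrame) -> pd.DataFrame:
    """Per-interval decomposition rates, % of initial pool C per day."""
    lengths = partitions["day_end"] - partitions["day_start"]
    if np.any(lengths <= 0):
        raise SchemaError("zero-length interval", column="day_end")
    out = partitions[["site_id", "point_id", "depth", "n_addition",
                      "day_start", "day_end"]].copy()
    for pool, col, init in (
        ("soc", "soc_c_ug", "soc_initial_c_ug"),
        ("litter", "litter_c_ug", "litter_initial_c_ug"),
        ("lignin_cbeta", "cbeta_c_ug", "cbeta_initial_c_ug"),
    ):
        out[f"rate_{pool}_pct_per_day"] = (
            100.0 * partitions[col] / partitions[init] / lengths)
    return out


def mean_rate_ratio(rates: pd.DataFrame, pool_a: str, pool_b: str) -> float:
    """Ratio of time-mean decomposition rates of two pools (a / b)."""
    a = rates[f"rate_{pool_a}_pct_per_day"].mean()
    b = rates[f"rate_{pool_b}_pct_per_day"].mean()
    return float(a / b)
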