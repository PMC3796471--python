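"""Excess attenuation relative to spherical spreading, and its dB algebra.

The core statistic: a point source loses 20·log10(d/d_ref) dB to geometric
(spherical) spreading; any measured loss beyond that is *excess attenuation*
(EA). Positive EA means the medium attenuates more than geometry predicts,
negative EA means channeling/enhancement (common over water at low
frequency).

Averaging convention: dB values are converted to linear pressure amplitude
(divide by 20), averaged, and converted back — the amplitude convention is
the one consistent with pressure (N/m²) averaging and is validated against
every recomputable printed summary cell. Min/max columns remain plain
extrema of the dB values; SD is reported on the dB scale.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

SPECIES_GRAND_MEAN_EA_DB = {
    # printed species-level grand means (dB), recomputable from the eight
    # per-distance substrate cells of each species via db_mean
    "Lithobates catesbeianus": 1.04,
    "Pelophylax perezi": 3.64,
}

#: Closed frequency-category ranges in kHz. Gaps (0.5–0.6, 3.0–3.5 exclusive)
#: are intentionally unassigned.
FREQUENCY_CATEGORIES = {
    "F1": (0.2, 0.5),
    "F2": (0.6, 1.0),
    "F3": (1.1, 2.0),
    "F4": (2.1, 3.0),
    "F5": (3.5, 5.0),
}


def spherical_loss(distance: float, reference: float = 0.5) -> float:
    """Spherical-spreading transmission loss, 20·log10(distance/reference) dB."""
    if distance <= 0 or reference <= 0:
        raise ValueError("distances must be positive")
    if distance < reference:
        raise ValueError("distance must be at least the reference distance")
    return 20.0 * np.log10(distance / reference)


def excess_attenuation(spl_ref: float, spl_far: float, distance: float,
                       reference: float = 0.5) -> float:
    """EA = measured loss (spl_ref − spl_far) minus the spherical prediction.

    Positive iff the sound attenuated at a higher rate than spherical
    spreading predicts for that distance.
    """
    return (spl_ref - spl_far) - spherical_loss(distance, reference)


def db_mean(values, convention: str = "amplitude") -> float:
    """Mean of dB values computed on the linear scale, reconverted to dB.

    "amplitude" (pressure, ÷20) is the study convention; "power" (÷10) is
    provided only to demonstrate that it does not reproduce the printed
    summary cells.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("db_mean of empty list")
    if not np.all(np.isfinite(v)):
        raise ValueError("db_mean requires finite values")
    k = {"amplitude": 20.0, "power": 10.0}[convention]
    return float(k * np.log10(np.mean(10.0 ** (v / k))))


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used for table output."""
    factor = 10.0 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def bin_frequency(frequency_hz: float) -> str | None:
    """Frequency category (F1–F5) of a tone, or None if the frequency falls
    in a gap between the closed ranges or outside 0.2–5 kHz."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    khz = frequency_hz / 1000.0
    for label, (lo, hi) in FREQUENCY_CATEGORIES.items():
        if lo - 1e-9 <= khz <= hi + 1e-9:
            return label
    return None


def ea_from_measurements(measurements: pd.DataFrame,
                         reference_distance: float = 0.5,
                         distances=(1.0, 2.0, 4.0, 8.0)) -> pd.DataFrame:
    """EA records from a calibrated SPL table.

    For each (locality, substrate, signal_id), the SPL at the reference
    distance is paired with each farther distance. Rows flagged invalid on
    either side of a pair are excluded (never zeroed); tone rows gain a
    frequency_category column.
    """
    df = measurements
    rows = []
    keys = ["locality", "substrate", "signal_id"]
    for (loc, sub, sig), grp in df.groupby(keys, sort=False):
        ref = grp[np.isclose(grp["distance"], reference_distance)]
        if ref.empty or not ref.iloc[0]["valid"]:
            continue
        spl_ref = float(ref.iloc[0]["spl_rms"])
        for d in distances:
            far = grp[np.isclose(grp["distance"], d)]
            if far.empty or not far.iloc[0]["valid"]:
                continue
            r = far.iloc[0]
            freq = r.get("frequency_hz")
            rows.append({
                "locality": loc, "substrate": sub, "distance": float(d),
                "signal_id": sig, "kind": r["kind"],
                "species": r.get("species"),
                "individual": r.get("individual"),
                "frequency_hz": freq,
                "frequency_category": (bin_frequency(freq)
                                       if freq is not None and np.isfinite(freq)
                                       else None),
                "excess_attenuation": excess_attenuation(
                    spl_ref, float(r["spl_rms"]), d, reference_distance),
            })
    return pd.DataFrame(rows)


def species_call_ea(ea_records: pd.DataFrame, min_valid_calls: int = 4
                    ) -> pd.DataFrame:
    """Per-cell call aggregates: the EAs of one species' individual calls at
    a given (locality, substrate, distance) are combined with db_mean.
    Cells with fewer than ``min_valid_calls`` contributing calls are flagged.
    """
    calls = ea_records[ea_records["kind"] == "call"]
    rows = []
    keys = ["species", "locality", "substrate", "distance"]
    for key, grp in calls.groupby(keys, sort=False):
        rows.append(dict(zip(keys, key)) | {
            "excess_attenuation": db_mean(grp["excess_attenuation"]),
            "n_calls": len(grp),
            "flagged": len(grp) < min_valid_calls,
        })
    return pd.DataFrame(rows)


def summarize(ea_records: pd.DataFrame, group_by: list[str],
              value: str = "excess_attenuation") -> pd.DataFrame:
    """Printed-table style summary: linear-domain mean (db_mean), dB-scale
    SD, raw dB extrema, and n per group. Empty groups are omitted."""
    rows = []
    for key, grp in ea_records.groupby(group_by, sort=False):
        v = grp[value].to_numpy(dtype=float)
        if v.size == 0:
            continue
        if not isinstance(key, tuple):
            key = (key,)
        rows.append(dict(zip(group_by, key)) | {
            "mean_db": db_mean(v),
            "sd_db": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "min_db": float(np.min(v)),
            "max_db": float(np.max(v)),
            "n": int(v.size),
        })
    return pd.DataFrame(rows)


def _data_path(name: str):
    return resources.files("anuraprop.data") / name


def load_tone_table() -> pd.DataFrame:
    """Published per-substrate/category EA summary for the pure tones
    (means, dB-scale SDs normalized to dot decimals, raw extrema)."""
    with resources.as_file(_data_path("tone_ea_summary.csv")) as p:
        return pd.read_csv(p)


def load_call_table() -> pd.DataFrame:
    """Published per-species/substrate/distance EA summary for the playback
    calls, including the per-substrate 'mean' rows."""
    with resources.as_file(_data_path("call_ea_summary.csv")) as p:
        return pd.read_csv(p)
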