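"""Genotype-specific phenological windows and environmental covariates (ECs).

The growing season of each genotype in each trial is split into three phases
anchored on heading (used as a proxy for anthesis, offset ``ANTHESIS_OFFSET``):

* V (vegetative): sowing to 21 days before heading,
* R (reproductive): the 31-day critical window from heading-20 to heading+10,
* G (grain filling): heading+11 to harvest.

All windows are inclusive day-offset ranges from sowing and tile
``[0, harvest]`` with no gaps or overlaps. Fifteen weather summaries are
computed per phase, giving 45 ECs per genotype-trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import PhenotypeTable, WeatherTable

logger = logging.getLogger(__name__)

#: days between heading and anthesis used to anchor the critical window
ANTHESIS_OFFSET = 0

#: frost-day threshold (degC, meteorological frost; days with tmin <= this count)
FROST_TMIN = 0.0

#: the 15 EC variables in catalogue order with their aggregator
EC_CATALOGUE: list[tuple[str, str]] = [
    ("PP", "sum"),      # cumulative precipitation, mm
    ("CC", "mean"),     # cloud cover, %
    ("ET", "sum"),      # cumulative evapotranspiration, mm
    ("FD", "count"),    # frost days: tmin <= 0 degC
    ("Tmax", "mean"),   # mean daily maximum temperature
    ("Tmean", "mean"),  # mean daily mean temperature
    ("Tgt25", "count"), # days with tmax > 25 degC
    ("Tmin", "mean"),   # mean daily minimum temperature
    ("Tlt15", "count"), # days with tmin < 15 degC
    ("Tlt4", "count"),  # days with tmin < 4 degC
    ("Q", "mean"),      # photothermal quotient: mean of daily sr/tmean (tmean > 0)
    ("RH", "mean"),     # relative humidity, %
    ("SR", "mean"),     # solar radiation, MJ m-2 d-1
    ("TA", "mean"),     # thermal amplitude: mean of daily tmax - tmin
    ("WS", "mean"),     # wind speed, m s-1
]

PHASES = ("V", "R", "G")

EC_COLUMNS = [f"{ph}{code}" for ph in PHASES for code, _ in EC_CATALOGUE]

EC_AGGREGATORS = {f"{ph}{code}": agg for ph in PHASES for code, agg in EC_CATALOGUE}


class PhaseError(ValueError):
    """Heading too close to sowing or harvest to define the three phases."""


@dataclass(frozen=True)
class PhaseWindows:
    """Inclusive day-offset windows from sowing for one genotype-trial."""

    v_start: int
    v_end: int
    r_start: int
    r_end: int
    g_start: int
    g_end: int

    def as_dict(self):
        return {"V": (self.v_start, self.v_end),
                "R": (self.r_start, self.r_end),
                "G": (self.g_start, self.g_end)}


def define_phases(sowing: int, heading: int, harvest: int) -> PhaseWindows:
    """Phase windows from day offsets (sowing must be 0-based origin).

    ``heading`` and ``harvest`` are day offsets from sowing. Requires
    sowing < heading-20 and heading+10 < harvest.
    """
    anth = heading + ANTHESIS_OFFSET
    if anth - 20 <= 0:
        raise PhaseError(f"heading day {heading} too close to sowing")
    if anth + 10 >= harvest:
        raise PhaseError(f"heading day {heading} too close to harvest {harvest}")
    return PhaseWindows(0, anth - 21, anth - 20, anth + 10, anth + 11, harvest)


# ---------------------------------------------------------------------------
# EC computation
# ---------------------------------------------------------------------------

def _daily_matrix(wdf: pd.DataFrame) -> np.ndarray:
    """Stack per-day EC integrands in catalogue order -> (n_days, 15, 2).

    Channel 0 holds the summand, channel 1 the divisor count (1 for plain
    sums/means; for Q only days with tmean > 0 contribute).
    """
    tmean = wdf["tmean"].to_numpy(float)
    tmin = wdf["tmin"].to_numpy(float)
    tmax = wdf["tmax"].to_numpy(float)
    qmask = tmean > 0
    q = np.where(qmask, wdf["sr"].to_numpy(float) / np.where(qmask, tmean, 1.0), 0.0)
    cols = {
        "PP": wdf["prec"].to_numpy(float),
        "CC": wdf["cc"].to_numpy(float),
        "ET": wdf["et"].to_numpy(float),
        "FD": (tmin <= FROST_TMIN).astype(float),
        "Tmax": tmax,
        "Tmean": tmean,
        "Tgt25": (tmax > 25.0).astype(float),
        "Tmin": tmin,
        "Tlt15": (tmin < 15.0).astype(float),
        "Tlt4": (tmin < 4.0).astype(float),
        "Q": q,
        "RH": wdf["rh"].to_numpy(float),
        "SR": wdf["sr"].to_numpy(float),
        "TA": tmax - tmin,
        "WS": wdf["ws"].to_numpy(float),
    }
    n = len(wdf)
    out = np.zeros((n, len(EC_CATALOGUE), 2))
    for k, (code, _) in enumerate(EC_CATALOGUE):
        out[:, k, 0] = cols[code]
        out[:, k, 1] = qmask.astype(float) if code == "Q" else 1.0
    return out


def _window_aggregate(prefix: np.ndarray, starts: np.ndarray,
                      ends: np.ndarray) -> np.ndarray:
    """Aggregate the 15 ECs over inclusive windows using prefix sums.

    ``prefix`` is the zero-padded cumulative sum of ``_daily_matrix`` along
    days: shape (n_days+1, 15, 2). Returns (len(starts), 15).
    """
    s = prefix[ends + 1] - prefix[starts]  # (m, 15, 2)
    vals = np.empty(s.shape[:2])
    for k, (code, agg) in enumerate(EC_CATALOGUE):
        if agg == "mean":
            cnt = s[:, k, 1]
            vals[:, k] = np.where(cnt > 0, s[:, k, 0] / np.maximum(cnt, 1), np.nan)
        else:  # sum or count
            vals[:, k] = s[:, k, 0]
    return vals


def compute_ec(weather_slice: pd.DataFrame, window: tuple[int, int],
               variable: str) -> float:
    """One EC value for one inclusive day-offset window of a weather slice.

    ``weather_slice`` must have one row per day, ordered, starting at
    day offset 0 (sowing); missing days inside the window raise.
    """
    a, b = window
    if a < 0 or b >= len(weather_slice):
        have = len(weather_slice)
        raise ValueError(
            f"window [{a},{b}] not covered by weather (days 0..{have-1})"
        )
    codes = [c for c, _ in EC_CATALOGUE]
    k = codes.index(variable)
    daily = _daily_matrix(weather_slice.iloc[a:b + 1])
    total = daily[:, k, :].sum(axis=0)
    if EC_CATALOGUE[k][1] == "mean":
        return float(total[0] / total[1]) if total[1] > 0 else float("nan")
    return float(total[0])


class ECMatrix:
    """Rows keyed by (genotype, trial); 45 named EC columns."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in EC_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing EC columns: {missing}")
        if df[EC_COLUMNS].isna().any().any():
            raise ValueError("EC matrix contains missing cells")
        self.df = df[["genotype", "trial", *EC_COLUMNS]].reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    @property
    def values(self) -> np.ndarray:
        return self.df[EC_COLUMNS].to_numpy(float)

    def metadata(self) -> dict:
        return {"columns": EC_COLUMNS, "aggregators": EC_AGGREGATORS,
                "frost_tmin": FROST_TMIN, "anthesis_offset": ANTHESIS_OFFSET}

    def write(self, path):
        import json
        self.df.to_csv(path, index=False)
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(self.metadata(), fh, indent=1)


def build_ec_matrix(pheno: PhenotypeTable, weather: WeatherTable,
                    on_phase_error: str = "raise") -> ECMatrix:
    """All 45 ECs for every (genotype, trial) cell of the phenotype table.

    Heading dates must be complete (run :func:`predict_heading` first).
    ``on_phase_error`` is ``"raise"`` or ``"drop"`` for records whose heading
    date falls too close to sowing or harvest.
    """
    cells = (
        pheno.df.groupby(["genotype", "trial"], sort=True)
        .agg(environment=("environment", "first"),
             sowing_date=("sowing_date", "first"),
             heading_date=("heading_date", "first"),
             harvest_date=("harvest_date", "first"))
        .reset_index()
    )
    if cells["heading_date"].isna().any():
        n = int(cells["heading_date"].isna().sum())
        raise ValueError(f"{n} genotype-trial cells have missing heading dates")
    rows, errors = [], []
    for env, grp in cells.groupby("environment", sort=True):
        wdf = weather.slice(env).sort_values("date")
        sow = pd.to_datetime(grp["sowing_date"].iloc[0])
        w0 = wdf["date"].iloc[0]
        day0 = int((sow - w0).days)
        if day0 < 0:
            raise ValueError(f"weather for {env} starts after sowing")
        wdf = wdf.iloc[day0:]
        dates = wdf["date"].to_numpy()
        if len(dates) > 1:
            gaps = np.diff(dates) != np.timedelta64(1, "D")
            if gaps.any():
                raise ValueError(f"weather for {env} has non-contiguous dates")
        prefix = np.zeros((len(wdf) + 1, len(EC_CATALOGUE), 2))
        prefix[1:] = np.cumsum(_daily_matrix(wdf), axis=0)
        heading = (pd.to_datetime(grp["heading_date"]) - sow).dt.days.to_numpy(int)
        harvest = (pd.to_datetime(grp["harvest_date"]) - sow).dt.days.to_numpy(int)
        ok = np.ones(len(grp), bool)
        anth = heading + ANTHESIS_OFFSET
        bad = (anth - 20 <= 0) | (anth + 10 >= harvest) | (harvest >= len(wdf))
        if bad.any():
            msg = [f"{g}/{t}" for g, t in
                   zip(grp["genotype"][bad], grp["trial"][bad])]
            if on_phase_error == "raise":
                raise PhaseError(f"invalid phase windows for cells: {msg[:10]}")
            errors.extend(msg)
            ok &= ~bad
        g = grp[ok]
        a = anth[ok]
        hv = harvest[ok]
        blocks = [
            _window_aggregate(prefix, np.zeros(len(g), int), a - 21),
            _window_aggregate(prefix, a - 20, a + 10),
            _window_aggregate(prefix, a + 11, hv),
        ]
        block = np.hstack(blocks)
        sub = pd.DataFrame(block, columns=EC_COLUMNS)
        sub.insert(0, "trial", g["trial"].to_numpy())
        sub.insert(0, "genotype", g["genotype"].to_numpy())
        rows.append(sub)
    if errors:
        logger.warning("dropped %d cells with invalid phase windows", len(errors))
    out = pd.concat(rows, ignore_index=True).sort_values(
        ["genotype", "trial"]).reset_index(drop=True)
    return ECMatrix(out)


# ---------------------------------------------------------------------------
# heading-date prediction
# ---------------------------------------------------------------------------

def predict_heading(pheno: PhenotypeTable, maturity_class: str | None = None,
                    max_iter: int = 100) -> tuple[PhenotypeTable, dict]:
    """Fill missing heading dates from a mixed model with random genotype,
    year, location, genotype-by-year and genotype-by-location effects.

    The model is fitted to days-from-sowing-to-heading on genotype-trial
    cells (per maturity class when ``maturity_class`` names a column).
    Missing cells get the conditional prediction; effects of levels never
    observed contribute zero. Observed cells are untouched.

    Returns the filled table and a report dict with the fill count and the
    variance components.
    """
    from .mm import IIDGroup, MixedModel

    df = pheno.df
    cells = (
        df.groupby(["genotype", "trial"], sort=True)
        .agg(year=("year", "first"), location=("location", "first"),
             sowing_date=("sowing_date", "first"),
             heading_date=("heading_date", "first"),
             **({maturity_class: (maturity_class, "first")} if maturity_class else {}))
        .reset_index()
    )
    cells["days"] = (
        pd.to_datetime(cells["heading_date"]) - pd.to_datetime(cells["sowing_date"])
    ).dt.days.astype(float)
    obs = cells["days"].notna()
    if not obs.any():
        raise ValueError("no observed heading dates")
    if cells.loc[obs, "year"].nunique() < 2 or cells.loc[obs, "location"].nunique() < 2:
        raise ValueError("need >=2 years and >=2 locations with observed heading")

    classes = ([None] if maturity_class is None
               else sorted(cells[maturity_class].unique()))
    report = {"n_filled": 0, "classes": {}}
    filled = cells["days"].copy()
    for cls in classes:
        sub = cells if cls is None else cells[cells[maturity_class] == cls]
        sobs = sub["days"].notna()
        train = sub[sobs]
        y = train["days"].to_numpy(float)
        g = train["genotype"].astype(str)
        a = train["year"].astype(str)
        l = train["location"].astype(str)
        terms = [
            ("genotype", IIDGroup(g)),
            ("year", IIDGroup(a)),
            ("location", IIDGroup(l)),
            ("gxy", IIDGroup(g + ":" + a)),
            ("gxl", IIDGroup(l + ":" + g)),
        ]
        model = MixedModel(y, np.ones((len(y), 1)), terms)
        res = model.fit(max_iter=max_iter)
        if not res.converged:
            raise RuntimeError(
                f"heading-date REML did not converge: {res.trace[-3:]}"
            )
        mu = float(res.beta[0])
        miss = sub[~sobs]
        if len(miss):
            mg = miss["genotype"].astype(str)
            ma = miss["year"].astype(str)
            ml = miss["location"].astype(str)
            pred = (mu
                    + res.blup_lookup("genotype", mg)
                    + res.blup_lookup("year", ma)
                    + res.blup_lookup("location", ml)
                    + res.blup_lookup("gxy", mg + ":" + ma)
                    + res.blup_lookup("gxl", ml + ":" + mg))
            filled.loc[miss.index] = pred
            report["n_filled"] += len(miss)
        report["classes"][cls or "pooled"] = {
            "variance_components": res.variance_components(),
            "n_obs": int(sobs.sum()), "n_missing": int((~sobs).sum()),
        }
    cells = cells.assign(days_filled=filled)
    new_heading = (
        pd.to_datetime(cells["sowing_date"])
        + pd.to_timedelta(np.round(cells["days_filled"]), unit="D")
    )
    lookup = dict(zip(zip(cells["genotype"], cells["trial"]), new_heading))
    out = df.copy()
    need = out["heading_date"].isna()
    out.loc[need, "heading_date"] = [
        lookup[(g, t)] for g, t in zip(out.loc[need, "genotype"], out.loc[need, "trial"])
    ]
    return PhenotypeTable(out, validate=False), report
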