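"""Synthetic multi-environment wheat breeding-program generator.

Emulates an unbalanced multi-year testing program — genotype turnover across
years, trials nested in (year, location, sowing-period) environments,
RCBD or alpha-lattice designs — with heritable heading dates, seasonal daily
weather, and plot yields generated from a known random-regression truth:

    yield = env + trial + rep + block + fixed EC effects
            + g0_i + sum_n g_{n,i} * EC_n(i, trial) + ge_ij [+ low-rank GEI]
            + plot error

with (g0, g1..gk) ~ MVN(0, Omega x K). Every stochastic component has its
own RNG stream derived from the master seed, so adding a generator never
perturbs the others, and every generator is fully deterministic under seed.

Markers are simulated as binomial(2, p) founders with random-mating progeny,
which yields the family structure of breeding germplasm; with
``n_founders >= n_genotypes`` each genotype is itself a founder and dosages
are independent binomial draws per locus.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import MarkerSet, PhenotypeTable, WeatherTable, environment_label
from .phenology import ECMatrix, build_ec_matrix

SOWING_DAY = {"PRE": (5, 1), "OPT": (6, 1), "POS": (7, 1)}
HEADING_BASE = {"PRE": 115, "OPT": 105, "POS": 95}


@dataclass
class SimulationConfig:
    """Study conditions for the generator (yields in kg/ha, dates in days)."""

    # population
    n_genotypes: int = 300
    n_loci: int = 1000
    n_founders: int = 40
    maf_range: tuple[float, float] = (0.1, 0.5)
    het_rate: float = 0.02
    # program layout
    n_years: int = 5
    start_year: int = 2014
    locations: tuple[str, ...] = ("LE", "DO")
    sowing_periods: tuple[str, ...] = ("PRE", "OPT")
    turnover: float = 0.4
    n_trials_per_env: int = 1
    design: str = "rcbd"            # "rcbd" | "alpha"
    n_reps: int = 2
    block_size: int = 10            # alpha designs only
    season_days: int = 185
    # heading-date model (days^2)
    hd_var_g: float = 25.0
    hd_var_year: float = 9.0
    hd_var_loc: float = 4.0
    hd_var_gy: float = 4.0
    hd_var_gl: float = 2.0
    hd_var_resid: float = 2.0
    heading_missing_trial_frac: float = 0.3
    heading_missing_geno_range: tuple[float, float] = (0.2, 0.9)
    # weather
    t_base: float = 16.5
    t_seasonal_amp: float = 6.5
    t_ar_phi: float = 0.65
    t_ar_sigma: float = 2.0
    t_year_sigma: float = 0.8
    diurnal_range: float = 10.0
    diurnal_sigma: float = 1.5
    wet_prob: float = 0.35
    rain_shape: float = 0.7
    rain_scale: float = 12.0
    # yield truth model (kg/ha scale)
    mu: float = 5000.0
    var_g0: float = 160000.0
    slope_var_frac: float = 0.30          # per active EC, x var_g0
    active_ecs: tuple[str, ...] = ("VTmax", "RPP", "VPP")
    fixed_ec_beta: tuple[float, ...] = (100.0, -80.0, 60.0)
    intercept_slope_cor: float = 0.0
    var_ge_iid: float = 15000.0
    var_year: float = 500000.0
    var_loc: float = 40000.0
    var_sow: float = 30000.0
    var_trial: float = 15000.0
    var_rep: float = 8000.0
    var_block: float = 6000.0
    var_plot: float = 80000.0
    # model-misspecification switch: low-rank GEI unexplained by the ECs
    misspecified: bool = False
    misspec_rank: int = 2
    misspec_var: float = 100000.0
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.turnover <= 1:
            raise ValueError("turnover must be in [0,1]")
        for name, v in asdict(self).items():
            if name.startswith(("var_", "hd_var")) and np.any(np.asarray(v) < 0):
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    @property
    def omega(self) -> np.ndarray:
        """True intercept+slope covariance of the random-regression truth."""
        k = len(self.active_ecs)
        sd = np.sqrt([self.var_g0] + [self.slope_var_frac * self.var_g0] * k)
        R = np.eye(k + 1)
        R[0, 1:] = R[1:, 0] = self.intercept_slope_cor
        Om = np.outer(sd, sd) * R
        if np.linalg.eigvalsh(Om).min() < -1e-8:
            raise ValueError("configured Omega is not PSD")
        return Om

    def variance_fractions(self) -> dict[str, float]:
        """Configured shares of the total plot-level variance."""
        k = len(self.active_ecs)
        gei = k * self.slope_var_frac * self.var_g0 + self.var_ge_iid \
            + (self.misspec_var if self.misspecified else 0.0)
        comps = {
            "genotype": self.var_g0,
            "gei": gei,
            "year": self.var_year,
            "location": self.var_loc,
            "sowing": self.var_sow,
            "trial": self.var_trial,
            "replicate": self.var_rep,
            "block": self.var_block if self.design == "alpha" else 0.0,
            "residual": self.var_plot,
        }
        tot = sum(comps.values())
        return {kk: v / tot for kk, v in comps.items()}


@dataclass
class GroundTruth:
    """Generative quantities recorded by :func:`simulate_yield`."""

    g0: pd.Series                     # true intercepts per genotype
    slopes: pd.DataFrame              # true slopes (genotype x active EC)
    omega: np.ndarray
    heading_true: pd.DataFrame        # genotype, trial, heading_day
    ec_z: pd.DataFrame                # standardized active ECs per cell
    ec_scaler: pd.DataFrame           # mean/sd used to standardize
    env_effects: pd.Series            # total environment-level effect
    year_effects: pd.Series           # realized year-effect draws
    loc_effects: pd.Series
    sow_effects: pd.Series
    ge_iid: pd.Series                 # i.i.d. GEI per (genotype, environment)
    variance_config: dict


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def simulate_markers(config: SimulationConfig) -> MarkerSet:
    """Founder-based biallelic dosage matrix of inbred lines.

    Founder dosages are binomial(2, p) with p uniform in ``maf_range``;
    non-founder genotypes are progeny of two random founders (one gamete
    each), giving realistic family relatedness. Lines are then inbred:
    heterozygous calls are resolved to a random homozygote except for a
    residual heterozygosity rate ``het_rate`` (selfed breeding lines).
    """
    if config.n_loci < 10:
        raise ValueError("n_loci must be >= 10")
    rng = config.rng(1)
    lo, hi = config.maf_range
    if lo <= 0 or hi >= 1:
        warnings.warn("frequency range touches 0/1; monomorphic loci possible")
    p = rng.uniform(lo, hi, config.n_loci)
    nf = min(config.n_founders, config.n_genotypes)
    founders = rng.binomial(2, p, size=(nf, config.n_loci)).astype(float)
    n_prog = config.n_genotypes - nf
    D = founders
    if n_prog > 0:
        pa = rng.integers(0, nf, n_prog)
        ma = rng.integers(0, nf, n_prog)
        gam1 = rng.binomial(1, founders[pa] / 2.0)
        gam2 = rng.binomial(1, founders[ma] / 2.0)
        D = np.vstack([founders, (gam1 + gam2).astype(float)])
    het = D == 1.0
    resolve = het & (rng.random(D.shape) > config.het_rate)
    D[resolve] = 2.0 * rng.binomial(1, 0.5, D.shape)[resolve]
    order = rng.permutation(config.n_genotypes)
    D = D[order]
    genotypes = [f"G{i+1:04d}" for i in range(config.n_genotypes)]
    loci = pd.DataFrame({
        "chrom": ["1A"] * config.n_loci,
        "pos": np.arange(1, config.n_loci + 1) * 1000,
        "ref": "A", "alt": "B",
    })
    return MarkerSet(D, genotypes, loci)


# ---------------------------------------------------------------------------
# program skeleton
# ---------------------------------------------------------------------------

def simulate_program(config: SimulationConfig) -> PhenotypeTable:
    """Plot-level skeleton (no yields): genotype turnover across years,
    trials in every (year, location, sowing-period) environment, RCBD or
    alpha-lattice layouts."""
    if config.turnover >= 1:
        raise ValueError("turnover must be < 1 so years stay connected")
    rng = config.rng(2)
    genotypes = [f"G{i+1:04d}" for i in range(config.n_genotypes)]
    n_per_year = max(2, round(
        config.n_genotypes / (1 + (config.n_years - 1) * config.turnover)))
    n_new = round(config.turnover * n_per_year) if config.n_years > 1 else 0
    cursor = n_per_year
    active = list(range(n_per_year))
    year_sets = [list(active)]
    for _ in range(1, config.n_years):
        keep = max(1, n_per_year - n_new)
        kept = list(rng.choice(active, size=min(keep, len(active)), replace=False))
        fresh = list(range(cursor, min(cursor + n_per_year - len(kept),
                                       config.n_genotypes)))
        cursor += len(fresh)
        active = kept + fresh
        if not active:
            raise ValueError("configuration produced a year with zero genotypes")
        year_sets.append(list(active))

    rows = []
    trial_no = 0
    for yi in range(config.n_years):
        year = config.start_year + yi
        ids = [genotypes[i] for i in year_sets[yi]]
        for loc in config.locations:
            for per in config.sowing_periods:
                m, d = SOWING_DAY[per]
                sowing = _dt.date(year, m, d)
                harvest = sowing + _dt.timedelta(days=config.season_days)
                parts = np.array_split(rng.permutation(ids),
                                       config.n_trials_per_env)
                for part in parts:
                    if len(part) == 0:
                        continue
                    trial_no += 1
                    tid = f"T{trial_no:03d}"
                    for rep in range(1, config.n_reps + 1):
                        order = rng.permutation(part)
                        if config.design == "alpha":
                            nb = max(1, int(np.ceil(len(order) / config.block_size)))
                            blocks = np.repeat(np.arange(1, nb + 1),
                                               config.block_size)[: len(order)]
                        else:
                            blocks = [np.nan] * len(order)
                        for g, b in zip(order, blocks):
                            rows.append((g, year, loc, per, tid, rep, b,
                                         sowing, harvest))
    df = pd.DataFrame(rows, columns=[
        "genotype", "year", "location", "sowing_period", "trial",
        "replicate", "block", "sowing_date", "harvest_date"])
    df["sowing_date"] = pd.to_datetime(df["sowing_date"])
    df["harvest_date"] = pd.to_datetime(df["harvest_date"])
    df["yield"] = np.nan
    return PhenotypeTable(df, validate=False)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def simulate_weather(skeleton: PhenotypeTable,
                     config: SimulationConfig) -> WeatherTable:
    """Daily weather per environment over its sowing-to-harvest span.

    One calendar series is generated per (year, location) and sliced per
    environment, so environments sharing a season share weather. Mean
    temperature follows a seasonal harmonic plus AR(1) noise; precipitation
    is a wet-day/gamma mixture; radiation, humidity, wind, cloud cover and
    evapotranspiration are derived with physically plausible couplings
    (ET increases with radiation and temperature).
    """
    if config.season_days < 60:
        raise ValueError("season must span >= 60 days")
    rng = config.rng(3)
    envs = (skeleton.df.groupby("environment")
            .agg(year=("year", "first"), location=("location", "first"),
                 sowing_date=("sowing_date", "first"),
                 harvest_date=("harvest_date", "first")).reset_index())
    year_temp = {y: rng.normal(0, config.t_year_sigma)
                 for y in sorted(envs["year"].unique())}
    year_rain = {y: rng.normal(0, 0.25)
                 for y in sorted(envs["year"].unique())}
    loc_temp = {l: rng.normal(0, 0.5) for l in sorted(set(envs["location"]))}

    series = {}
    for (year, loc), _ in envs.groupby(["year", "location"]):
        start = _dt.date(int(year), 4, 1)
        end = _dt.date(int(year) + 1, 1, 31)
        dates = pd.date_range(start, end, freq="D")
        doy = dates.day_of_year.to_numpy(float)
        n = len(dates)
        harm = config.t_base - config.t_seasonal_amp * np.cos(
            2 * np.pi * (doy - 196) / 365.25)
        ar = np.zeros(n)
        eps = rng.normal(0, config.t_ar_sigma, n)
        for i in range(1, n):
            ar[i] = config.t_ar_phi * ar[i - 1] + eps[i]
        tmean = harm + year_temp[year] + loc_temp[loc] + ar
        amp = np.maximum(config.diurnal_range
                         + rng.normal(0, config.diurnal_sigma, n), 0.0)
        tmax = tmean + amp / 2.0
        tmin = tmean - amp / 2.0
        wet = rng.random(n) < config.wet_prob
        prec = np.where(
            wet,
            rng.gamma(config.rain_shape, config.rain_scale, n)
            * np.exp(year_rain[year]),
            0.0)
        sr = np.clip(16 + 9 * np.cos(2 * np.pi * (doy - 356) / 365.25)
                     + rng.normal(0, 2.0, n), 1.0, 35.0)
        sr = np.where(wet, sr * 0.55, sr)
        cc = np.clip(30 + 45 * wet.astype(float) + rng.normal(0, 10, n), 0, 100)
        rh = np.clip(72 + 12 * wet.astype(float) - 0.8 * (tmean - 15)
                     + rng.normal(0, 5, n), 25, 100)
        ws = np.exp(rng.normal(1.0, 0.4, n))
        et = np.clip(0.013 * (tmean + 17.8) * sr / 2.45
                     + rng.normal(0, 0.2, n), 0.0, None)
        series[(year, loc)] = pd.DataFrame({
            "date": dates, "prec": prec, "tmax": tmax, "tmin": tmin,
            "tmean": tmean, "rh": rh, "sr": sr, "ws": ws, "et": et, "cc": cc})

    frames = []
    for _, row in envs.iterrows():
        s = series[(row["year"], row["location"])]
        sow = pd.Timestamp(row["sowing_date"])
        harv = pd.Timestamp(row["harvest_date"])
        sl = s[(s["date"] >= sow) & (s["date"] <= harv)].copy()
        sl.insert(0, "environment", row["environment"])
        frames.append(sl)
    return WeatherTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# phenology
# ---------------------------------------------------------------------------

def simulate_phenology(skeleton: PhenotypeTable, markers: MarkerSet,
                       config: SimulationConfig) -> pd.DataFrame:
    """Heading (and harvest) day per genotype-trial cell.

    heading = trial base + year + location + genotype (MVN with GRM
    covariance) + GxY + GxL + noise, rounded to whole days; a configurable
    fraction of genotypes in a fraction of trials is masked as missing.
    Returns columns: genotype, trial, heading_day (true), heading_obs
    (NaN where masked), harvest_day.
    """
    from .mm import vanraden_grm

    rng = config.rng(4)
    cells = (skeleton.df.groupby(["genotype", "trial"], sort=True)
             .agg(year=("year", "first"), location=("location", "first"),
                  sowing_period=("sowing_period", "first")).reset_index())
    genos = markers.genotypes
    gi = {g: i for i, g in enumerate(genos)}
    K = vanraden_grm(markers).K
    L = np.linalg.cholesky(K + 1e-8 * np.eye(len(K)))
    g_eff = np.sqrt(config.hd_var_g) * (L @ rng.standard_normal(len(K)))
    years = sorted(cells["year"].unique())
    locs = sorted(cells["location"].unique())
    y_eff = dict(zip(years, rng.normal(0, np.sqrt(config.hd_var_year), len(years))))
    l_eff = dict(zip(locs, rng.normal(0, np.sqrt(config.hd_var_loc), len(locs))))
    gy = {}
    gl = {}
    idx = cells["genotype"].map(gi).to_numpy()
    base = cells["sowing_period"].map(HEADING_BASE).to_numpy(float)
    vals = base + g_eff[idx]
    vals += cells["year"].map(y_eff).to_numpy()
    vals += cells["location"].map(l_eff).to_numpy()
    for key_cols, eff, var in [("year", gy, config.hd_var_gy),
                               ("location", gl, config.hd_var_gl)]:
        keys = list(zip(cells["genotype"], cells[key_cols]))
        for k in dict.fromkeys(keys):
            eff[k] = rng.normal(0, np.sqrt(var))
        vals += np.asarray([eff[k] for k in keys])
    vals += rng.normal(0, np.sqrt(config.hd_var_resid), len(cells))
    heading = np.round(vals)
    lo, hi = 40, config.season_days - 20
    n_clip = int(((heading < lo) | (heading > hi)).sum())
    if n_clip:
        warnings.warn(f"clipped {n_clip} heading dates into [{lo},{hi}]")
    heading = np.clip(heading, lo, hi)

    obs = heading.astype(float).copy()
    trials = sorted(cells["trial"].unique())
    n_mask_trials = round(config.heading_missing_trial_frac * len(trials))
    mask_trials = sorted(rng.choice(trials, n_mask_trials, replace=False))
    for t in mask_trials:
        rowsel = np.nonzero((cells["trial"] == t).to_numpy())[0]
        frac = rng.uniform(*config.heading_missing_geno_range)
        m = rng.choice(rowsel, round(frac * len(rowsel)), replace=False)
        obs[m] = np.nan
    return pd.DataFrame({
        "genotype": cells["genotype"], "trial": cells["trial"],
        "heading_day": heading.astype(int), "heading_obs": obs,
        "harvest_day": config.season_days,
    })


# ---------------------------------------------------------------------------
# yield
# ---------------------------------------------------------------------------

def _attach_dates(skeleton: PhenotypeTable, phen: pd.DataFrame,
                  which: str) -> pd.DataFrame:
    df = skeleton.df.merge(phen[["genotype", "trial", which, "harvest_day"]],
                           on=["genotype", "trial"], how="left")
    df["heading_date"] = (pd.to_datetime(df["sowing_date"])
                          + pd.to_timedelta(df[which], unit="D"))
    return df.drop(columns=[which, "harvest_day"])


def simulate_yield(skeleton: PhenotypeTable, markers: MarkerSet,
                   weather: WeatherTable, phenology: pd.DataFrame,
                   config: SimulationConfig
                   ) -> tuple[PhenotypeTable, GroundTruth, ECMatrix]:
    """Plot yields from the random-regression truth model.

    Returns the finished plot table (yields; observed heading with the
    masking pattern), the ground truth, and the realized EC matrix built
    from the *true* heading dates.
    """
    from .mm import vanraden_grm

    rng = config.rng(5)
    Om = config.omega
    np.linalg.cholesky(Om + 1e-12 * np.eye(len(Om)))  # PSD check before sampling

    truth_pheno = PhenotypeTable(
        _attach_dates(skeleton, phenology, "heading_day"), validate=False)
    ecm = build_ec_matrix(truth_pheno, weather)
    active = list(config.active_ecs)
    sub = ecm.df[["genotype", "trial", *active]].copy()
    mean = sub[active].mean()
    sd = sub[active].std(ddof=0).replace(0.0, 1.0)
    ecz = (sub[active] - mean) / sd
    scaler = pd.DataFrame({"mean": mean, "sd": sd})

    K = vanraden_grm(markers).K
    genos = markers.genotypes
    Lk = np.linalg.cholesky(K + 1e-8 * np.eye(len(K)))
    Lo = np.linalg.cholesky(Om + 1e-12 * np.eye(len(Om)))
    coefs = Lk @ rng.standard_normal((len(genos), len(Om))) @ Lo.T
    g0 = pd.Series(coefs[:, 0], index=genos)
    slopes = pd.DataFrame(coefs[:, 1:], index=genos, columns=active)

    df = skeleton.df.copy()
    envs = sorted(df["environment"].unique())
    years = sorted(df["year"].unique())
    locs = sorted(df["location"].unique())
    sows = sorted(df["sowing_period"].unique())
    y_eff = dict(zip(years, rng.normal(0, np.sqrt(config.var_year), len(years))))
    l_eff = dict(zip(locs, rng.normal(0, np.sqrt(config.var_loc), len(locs))))
    s_eff = dict(zip(sows, rng.normal(0, np.sqrt(config.var_sow), len(sows))))
    trials = sorted(df["trial"].unique())
    t_eff = dict(zip(trials, rng.normal(0, np.sqrt(config.var_trial), len(trials))))
    rep_keys = sorted(set(zip(df["trial"], df["replicate"])))
    r_eff = {k: rng.normal(0, np.sqrt(config.var_rep)) for k in rep_keys}
    if config.design == "alpha":
        blk_keys = sorted(set(zip(df["trial"], df["replicate"],
                                  df["block"].astype(str))))
        b_eff = {k: rng.normal(0, np.sqrt(config.var_block)) for k in blk_keys}
    ge_keys = sorted(set(zip(df["genotype"], df["environment"])))
    ge = pd.Series({k: rng.normal(0, np.sqrt(config.var_ge_iid))
                    for k in ge_keys})

    if config.misspecified:
        lam = rng.normal(0, 1.0, (len(envs), config.misspec_rank))
        lam /= np.sqrt(np.mean(np.sum(lam ** 2, axis=1)))
        fac = (Lk @ rng.standard_normal((len(genos), config.misspec_rank))
               * np.sqrt(config.misspec_var))
        mis = pd.DataFrame(fac @ lam.T, index=genos, columns=envs)

    cellkey = pd.MultiIndex.from_frame(sub[["genotype", "trial"]])
    ecz_idx = pd.DataFrame(ecz.to_numpy(), index=cellkey, columns=active)
    rowkey = pd.MultiIndex.from_frame(df[["genotype", "trial"]])
    Z = ecz_idx.loc[rowkey].to_numpy()
    beta = np.asarray(config.fixed_ec_beta[: len(active)], float)
    if len(beta) < len(active):
        beta = np.pad(beta, (0, len(active) - len(beta)))
    slope_mat = slopes.loc[df["genotype"]].to_numpy()

    env_part = (df["year"].map(y_eff).to_numpy()
                + df["location"].map(l_eff).to_numpy()
                + df["sowing_period"].map(s_eff).to_numpy())
    y = (config.mu + env_part
         + df["trial"].map(t_eff).to_numpy()
         + np.asarray([r_eff[k] for k in zip(df["trial"], df["replicate"])])
         + Z @ beta
         + g0.loc[df["genotype"]].to_numpy()
         + np.sum(slope_mat * Z, axis=1)
         + ge.loc[list(zip(df["genotype"], df["environment"]))].to_numpy())
    if config.design == "alpha":
        y += np.asarray([b_eff[k] for k in zip(df["trial"], df["replicate"],
                                               df["block"].astype(str))])
    if config.misspecified:
        y += np.asarray([mis.at[g, e] for g, e in
                         zip(df["genotype"], df["environment"])])
    y += rng.normal(0, np.sqrt(config.var_plot), len(df))
    out = _attach_dates(skeleton, phenology, "heading_obs")
    out["yield"] = y
    env_series = pd.Series(
        {e: y_eff[int(e.split("_")[0])] + l_eff[e.split("_")[1]]
         + s_eff[e.split("_")[2]] for e in envs})
    truth = GroundTruth(
        g0=g0, slopes=slopes, omega=Om,
        heading_true=phenology[["genotype", "trial", "heading_day"]].copy(),
        ec_z=pd.concat([sub[["genotype", "trial"]], ecz], axis=1),
        ec_scaler=scaler, env_effects=env_series,
        year_effects=pd.Series(y_eff), loc_effects=pd.Series(l_eff),
        sow_effects=pd.Series(s_eff), ge_iid=ge,
        variance_config=config.variance_fractions(),
    )
    return PhenotypeTable(out, validate=False), truth, ecm


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    markers: MarkerSet
    pheno: PhenotypeTable
    weather: WeatherTable
    phenology: pd.DataFrame
    truth: GroundTruth
    ec_true: ECMatrix


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator chain under one config."""
    markers = simulate_markers(config)
    skeleton = simulate_program(config)
    weather = simulate_weather(skeleton, config)
    phen = simulate_phenology(skeleton, markers, config)
    pheno, truth, ecm = simulate_yield(skeleton, markers, weather, phen, config)
    return SimulatedDataset(config, markers, pheno, weather, phen, truth, ecm)
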