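"""Ground-truth generator: a signal-duration-decoding transcriptional cascade.

The simulator reproduces the statistical and kinetic structure the analysis
pipeline assumes, with known labels:

* a stimulus-activated kinase whose activity follows
  ``dE/dt = k_act*u(t)*(1-E) - k_deact*E`` with ``u(t)=1`` while the stimulus
  is present.  Deactivation is fast (half-decay <= 1 h), so activity returns
  near baseline within about an hour of stimulus withdrawal — this is what
  makes transient and sustained treatment transcriptionally distinguishable.
* primary response genes transcribed directly from kinase activity through a
  delayed Hill gate: ``dm/dt = a0 + a*h(E(t-tau)) - dm_eff*m``.  They do not
  require new protein synthesis, so a translation block (cycloheximide, CHX)
  leaves them inducible.
* primary transcription-factor (TF) proteins: ``dp/dt = k_tl*m - dp_rate*p``
  (``k_tl = 0`` under CHX, block starting 0.5 h before the stimulus).
* secondary response genes driven by a TF protein instead of the kinase;
  blocking translation abolishes their induction.
* superinduction: some primary genes carry a destabilising link from a
  translation-dependent secondary repressor R, ``dm_eff = dm*(1 + gamma*R)``.
  Under CHX the repressor is lost and those genes overshoot; under CHX alone
  they drift up without any stimulus, which is the classic confound the
  downstream primary/secondary classifier has to survive.

Measurement adds a microarray-like layer on the log2 scale: per-probe
affinity, per-array additive shift, an intensity-dependent curvature
distortion (for the loess stage to remove) and Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "StimulusProtocol",
    "CascadeSpec",
    "NoiseModel",
    "StudyConfig",
    "build_default_cascade",
    "simulate_kinetics",
    "kinase_activity",
    "measure",
    "generate_study",
    "default_protocols",
]

# harvest-time grids: the printed designs give counts and ranges; the exact
# times below satisfy them and cover the early/delayed/late windows.
DURATION_SUSTAINED_TIMES = (1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 14.0)
DURATION_TRANSIENT_TIMES = (1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 14.0)
DURATION_UNTREATED_TIMES = (0.0,) + DURATION_SUSTAINED_TIMES
SUSTAINED_SERIES_TIMES = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 14.0)
SUSTAINED_SERIES_UNTREATED_TIMES = (0.0,) + SUSTAINED_SERIES_TIMES
CHX_SERIES_TIMES = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 10.0)

CHX_PRETREAT_H = 0.5  # translation blocked from t = -0.5 h

GENE_COLUMNS = [
    "true_class", "alpha0", "alpha", "hill_n", "hill_k", "tau", "delta_m",
    "k_tl", "delta_p", "driver_id", "gamma", "repressor_id",
]


class CascadeConfigError(ValueError):
    """Raised for inconsistent cascade specifications."""


@dataclass(frozen=True)
class StimulusProtocol:
    """One arm of a time-series experiment.

    duration_h
        Hours the stimulus is present from t=0 (0 = untreated, 1 = transient,
        14 = sustained).
    chx
        If True, translation is blocked from t = -CHX_PRETREAT_H onward.
    sample_times_h
        Ordered harvest times (h).
    """

    duration_h: float
    sample_times_h: tuple[float, ...]
    n_replicates: int = 2
    chx: bool = False
    experiment_id: str = "duration_series"

    def __post_init__(self):
        times = tuple(float(t) for t in self.sample_times_h)
        object.__setattr__(self, "sample_times_h", times)
        if self.duration_h < 0:
            raise CascadeConfigError("duration_h must be >= 0")
        if self.n_replicates < 1:
            raise CascadeConfigError("n_replicates must be >= 1")
        if len(times) == 0:
            raise CascadeConfigError("sample_times_h must be non-empty")
        arr = np.asarray(times)
        if (np.diff(arr) <= 0).any():
            raise CascadeConfigError("sample_times_h must be strictly increasing")
        if arr[0] < 0 or arr[-1] > 14:
            raise CascadeConfigError("sample_times_h must lie in [0, 14] h")


@dataclass
class CascadeSpec:
    """Gene network + kinetics.  ``genes`` is indexed by gene_id with columns
    GENE_COLUMNS; ``k_act``/``k_deact`` are the shared kinase rates (1/h)."""

    genes: pd.DataFrame
    k_act: float = 9.0
    k_deact: float = 2.3

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        g = self.genes
        missing = [c for c in GENE_COLUMNS if c not in g.columns]
        if missing:
            raise CascadeConfigError(f"gene table missing columns: {missing}")
        if g.index.duplicated().any():
            raise CascadeConfigError("duplicate gene ids")
        if self.k_act <= 0 or self.k_deact <= 0:
            raise CascadeConfigError("kinase rates must be positive")
        if np.log(2) / self.k_deact > 1.0 + 1e-12:
            raise CascadeConfigError(
                "kinase half-decay ln2/k_deact must be <= 1 h so transient "
                "activity returns near baseline within ~1 h"
            )
        bad_class = set(g["true_class"]) - {"primary", "secondary", "unresponsive"}
        if bad_class:
            raise CascadeConfigError(f"unknown true_class values: {bad_class}")
        for col in ("alpha0", "delta_m", "k_tl", "delta_p", "hill_n", "hill_k", ):
            if (g[col] <= 0).any():
                raise CascadeConfigError(f"column {col} must be strictly positive")
        if (g["alpha"] < 0).any() or (g["tau"] < 0).any() or (g["gamma"] < 0).any():
            raise CascadeConfigError("alpha, tau and gamma must be non-negative")
        primaries = set(g.index[g["true_class"] == "primary"])
        secondaries = set(g.index[g["true_class"] == "secondary"])
        sec = g[g["true_class"] == "secondary"]
        bad = [i for i, d in sec["driver_id"].items() if d not in primaries]
        if bad:
            raise CascadeConfigError(
                f"secondary genes with driver_id not a primary gene: {bad}"
            )
        sup = g[(g["true_class"] == "primary") & g["repressor_id"].notna()]
        bad = [i for i, r in sup["repressor_id"].items() if r not in secondaries]
        if bad:
            raise CascadeConfigError(
                f"superinduced primaries with repressor_id not a secondary: {bad}"
            )
        # acyclicity of the dependency graph primary -> secondary -> primary:
        # a superinduced primary must not (transitively) drive its own
        # repressor, otherwise the staged integration order breaks down.
        # Edges: driver -> secondary, repressor secondary -> superinduced.
        edges: dict[str, list[str]] = {i: [] for i in g.index}
        for i, d in sec["driver_id"].items():
            edges[d].append(i)
        for i, r in sup["repressor_id"].items():
            edges[r].append(i)
        state: dict[str, int] = {}

        def visit(node: str, stack: list[str]) -> None:
            state[node] = 1
            for nxt in edges[node]:
                if state.get(nxt) == 1:
                    raise CascadeConfigError(
                        f"cycle among driver/repressor links via {stack + [node, nxt]}"
                    )
                if state.get(nxt) != 2:
                    visit(nxt, stack + [node])
            state[node] = 2

        for node in g.index:
            if state.get(node) != 2:
                visit(node, [])
        # staged integration additionally requires superinduced primaries
        # not to act as drivers
        sup_drivers = set(sec["driver_id"]) & set(sup.index)
        if sup_drivers:
            raise CascadeConfigError(
                f"superinduced primaries may not drive secondaries: {sorted(sup_drivers)}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    def basal_mrna(self) -> pd.Series:
        """Untreated steady-state mRNA per gene (kinase off, fixed point)."""
        return _steady_state(self)["m"]


@dataclass(frozen=True)
class NoiseModel:
    """Microarray-like measurement model on the log2 scale.

    sigma                additive Gaussian sd (log2 units)
    probe_scale_sdlog    sd of ln(probe affinity); affinities are log-normal
    array_shift_sd       sd of the per-array additive log2 offset
    curvature_sd         sd of the per-array curvature coefficient; the
                         distortion added is q * ((y - 8)/4)**2, a smooth
                         intensity-dependent bias on the MA scale that the
                         loess stage is expected to remove
    floor                mRNA floor before log2 (avoids log of <=0)
    """

    sigma: float = 0.1
    probe_scale_sdlog: float = 0.25
    array_shift_sd: float = 0.3
    curvature_sd: float = 0.05
    floor: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise CascadeConfigError("sigma must be >= 0")
        if self.probe_scale_sdlog < 0 or self.floor <= 0:
            raise CascadeConfigError("invalid noise model parameters")

    def probe_scales(self, n_genes: int) -> np.ndarray:
        """Per-gene multiplicative probe affinities (>0), fixed by rng_seed."""
        rng = np.random.default_rng(np.random.SeedSequence(self.rng_seed, spawn_key=(0,)))
        return np.exp(rng.normal(0.0, self.probe_scale_sdlog, size=n_genes))


# ---------------------------------------------------------------------------
# cascade construction


def _hill(x, n, k):
    x = np.maximum(x, 0.0)
    xn = x ** n
    return xn / (xn + k ** n)


def build_default_cascade(
    n_primary: int,
    n_secondary: int,
    n_unresponsive: int,
    seed: int,
    superinduced_fraction: float = 0.5,
    k_act: float = 9.0,
    k_deact: float = 2.3,
) -> CascadeSpec:
    """Draw a labelled cascade whose responsive genes span early (<2 h),
    delayed (2-4 h) and late (>4 h) peak-time classes.

    Early and delayed primaries get their peak-and-decline shape from a
    repressor link to a fast secondary gene (superinduction under CHX comes
    for free); late primaries rise monotonically through the time course.
    ``superinduced_fraction`` is the fraction of eligible (non-TF) primaries
    carrying a repressor link; it is only realisable when secondaries exist.
    """
    if min(n_primary, n_secondary, n_unresponsive) < 0:
        raise CascadeConfigError("gene counts must be >= 0")
    if n_secondary > 0 and n_primary == 0:
        raise CascadeConfigError("secondary genes require at least one primary TF")
    rng = np.random.default_rng(seed)
    e_inf = k_act / (k_act + k_deact)
    rows: list[dict] = []

    def base_row(gene_id, true_class):
        return dict(
            gene_id=gene_id, true_class=true_class, driver_id=None,
            gamma=0.0, repressor_id=None,
        )

    # --- primaries -------------------------------------------------------
    # a small pool of fast TFs drives the secondary layer; remaining
    # primaries are split into early/delayed/late peak-time targets.
    n_tf = 0 if n_secondary == 0 else max(1, min(n_primary, round(0.08 * n_primary) or 1))
    primary_ids = [f"P{i:03d}" for i in range(n_primary)]
    tf_ids = primary_ids[:n_tf]
    rest = primary_ids[n_tf:]
    n_rest = len(rest)
    n_early = round(0.20 * n_rest)
    n_delayed = round(0.30 * n_rest)
    targets = (["early"] * n_early + ["delayed"] * n_delayed
               + ["late"] * (n_rest - n_early - n_delayed))

    for gid in tf_ids:
        row = base_row(gid, "primary")
        m0 = rng.uniform(5, 25)
        fold = rng.uniform(12, 25)
        row.update(
            delta_m=rng.uniform(0.8, 1.5), tau=rng.uniform(0.0, 0.2),
            hill_n=rng.integers(2, 5), hill_k=e_inf * rng.uniform(0.25, 0.45),
            k_tl=rng.uniform(2.0, 5.0), delta_p=rng.uniform(0.8, 1.4),
        )
        row["alpha0"] = m0 * row["delta_m"]
        row["alpha"] = (fold - 1) * row["alpha0"]
        rows.append(row)

    eligible_super = []  # non-TF primaries that may carry a repressor link
    for gid, target in zip(rest, targets):
        row = base_row(gid, "primary")
        if target == "early":
            m0, fold = rng.uniform(5, 30), rng.uniform(8, 20)
            row.update(delta_m=rng.uniform(1.2, 2.0), tau=rng.uniform(0.0, 0.3))
            wants_repressor = True
        elif target == "delayed":
            m0, fold = rng.uniform(20, 150), rng.uniform(5, 12)
            row.update(delta_m=rng.uniform(0.6, 1.2), tau=rng.uniform(0.8, 2.0))
            wants_repressor = True
        else:  # late
            m0, fold = rng.uniform(30, 300), rng.uniform(3, 10)
            row.update(delta_m=rng.uniform(0.15, 0.45), tau=rng.uniform(2.5, 6.0))
            wants_repressor = rng.uniform() < 0.25  # some late peak-decliners
        row.update(
            hill_n=rng.integers(2, 5), hill_k=e_inf * rng.uniform(0.25, 0.45),
            k_tl=rng.uniform(0.5, 2.0), delta_p=rng.uniform(0.4, 0.9),
        )
        row["alpha0"] = m0 * row["delta_m"]
        row["alpha"] = (fold - 1) * row["alpha0"]
        if wants_repressor:
            eligible_super.append((gid, target))
        rows.append(row)

    # --- secondaries -----------------------------------------------------
    secondary_ids = [f"S{i:03d}" for i in range(n_secondary)]
    n_repressors = min(2, n_secondary)
    for j, gid in enumerate(secondary_ids):
        row = base_row(gid, "secondary")
        driver = tf_ids[int(rng.integers(len(tf_ids)))]
        row["driver_id"] = driver
        if j < n_repressors:  # fast repressor genes
            m0, fold = rng.uniform(10, 40), rng.uniform(8, 16)
            row.update(
                delta_m=rng.uniform(1.2, 1.8), tau=rng.uniform(0.0, 0.2),
                k_tl=rng.uniform(2.0, 4.0), delta_p=rng.uniform(1.0, 1.6),
            )
        else:
            m0, fold = rng.uniform(20, 200), rng.uniform(4, 16)
            row.update(
                delta_m=rng.uniform(0.2, 0.6), tau=rng.uniform(0.0, 1.0),
                k_tl=rng.uniform(0.5, 2.0), delta_p=rng.uniform(0.4, 0.9),
            )
        row["alpha0"] = m0 * row["delta_m"]
        row["alpha"] = (fold - 1) * row["alpha0"]
        row.update(hill_n=4, hill_k=np.nan)  # hill_k filled from driver below
        rows.append(row)

    # --- unresponsive ----------------------------------------------------
    for i in range(n_unresponsive):
        row = base_row(f"U{i:03d}", "unresponsive")
        # stable genes span the array's full dynamic range — the brightest
        # probes on a real array are housekeeping transcripts, and they are
        # what anchors the MA loess fit at high intensity
        m0 = 2.0 ** rng.uniform(4.5, 12.0)
        row.update(
            delta_m=rng.uniform(0.3, 1.5), tau=0.0, alpha=0.0,
            hill_n=2, hill_k=1.0, k_tl=1.0, delta_p=1.0,
        )
        row["alpha0"] = m0 * row["delta_m"]
        rows.append(row)

    genes = pd.DataFrame(rows).set_index("gene_id")

    # secondary Hill thresholds sit between the driver's basal and fully
    # induced protein levels, so basal TF protein barely activates them
    if n_secondary:
        for gid in secondary_ids:
            d = genes.loc[gid, "driver_id"]
            m_ss = (genes.loc[d, "alpha0"] + genes.loc[d, "alpha"]
                    * _hill(e_inf, genes.loc[d, "hill_n"], genes.loc[d, "hill_k"])
                    ) / genes.loc[d, "delta_m"]
            p_ss = genes.loc[d, "k_tl"] * m_ss / genes.loc[d, "delta_p"]
            genes.loc[gid, "hill_k"] = p_ss * rng.uniform(0.30, 0.50)

    # --- superinduction links -------------------------------------------
    if n_secondary and eligible_super and superinduced_fraction > 0:
        n_super = round(superinduced_fraction * len(eligible_super))
        order = rng.permutation(len(eligible_super))[:n_super]
        repressor_pool = secondary_ids[:n_repressors]
        # repressor protein level under sustained stimulation, for scaling gamma
        r_ss = {}
        for rid in repressor_pool:
            d = genes.loc[rid, "driver_id"]
            m_tf = (genes.loc[d, "alpha0"] + genes.loc[d, "alpha"]
                    * _hill(e_inf, genes.loc[d, "hill_n"], genes.loc[d, "hill_k"])
                    ) / genes.loc[d, "delta_m"]
            p_tf = genes.loc[d, "k_tl"] * m_tf / genes.loc[d, "delta_p"]
            m_r = (genes.loc[rid, "alpha0"] + genes.loc[rid, "alpha"]
                   * _hill(p_tf, genes.loc[rid, "hill_n"], genes.loc[rid, "hill_k"])
                   ) / genes.loc[rid, "delta_m"]
            r_ss[rid] = genes.loc[rid, "k_tl"] * m_r / genes.loc[rid, "delta_p"]
        for pos in order:
            gid, target = eligible_super[pos]
            rid = repressor_pool[int(rng.integers(len(repressor_pool)))]
            strength = rng.uniform(2.0, 4.0) if target == "early" else rng.uniform(1.5, 3.0)
            genes.loc[gid, "repressor_id"] = rid
            genes.loc[gid, "gamma"] = strength / r_ss[rid]

    genes = genes[GENE_COLUMNS].astype(
        {c: float for c in ("alpha0", "alpha", "hill_n", "hill_k", "tau",
                            "delta_m", "k_tl", "delta_p", "gamma")}
    )
    return CascadeSpec(genes=genes, k_act=k_act, k_deact=k_deact)


# ---------------------------------------------------------------------------
# kinetics


def kinase_activity(t, duration_h: float, k_act: float, k_deact: float):
    """Closed-form kinase activity for piecewise-constant stimulus u(t).

    E(0)=0; on-phase relaxes to k_act/(k_act+k_deact), off-phase decays
    with rate k_deact.  Vectorised over t.
    """
    t = np.asarray(t, dtype=float)
    e_inf = k_act / (k_act + k_deact)
    ktot = k_act + k_deact
    on = np.clip(t, 0.0, duration_h)
    e_on = e_inf * (1.0 - np.exp(-ktot * on))
    off = np.maximum(t - duration_h, 0.0)
    out = e_on * np.exp(-k_deact * off)
    return np.where(t <= 0, 0.0, out)


def _steady_state(spec: CascadeSpec) -> pd.DataFrame:
    """Untreated fixed point (E=0) solved in cascade order."""
    g = spec.genes
    out = pd.DataFrame(index=g.index, columns=["m", "p"], dtype=float)
    prim = g["true_class"] != "secondary"
    # E=0 -> hill term 0 for primaries; superinduced have dm_eff via repressor R0
    out.loc[prim, "m"] = g.loc[prim, "alpha0"] / g.loc[prim, "delta_m"]
    out.loc[prim, "p"] = g.loc[prim, "k_tl"] * out.loc[prim, "m"] / g.loc[prim, "delta_p"]
    sec = g.index[g["true_class"] == "secondary"]
    for gid in sec:
        row = g.loc[gid]
        p_drv = out.loc[row["driver_id"], "p"]
        out.loc[gid, "m"] = (row["alpha0"] + row["alpha"]
                             * _hill(p_drv, row["hill_n"], row["hill_k"])) / row["delta_m"]
        out.loc[gid, "p"] = row["k_tl"] * out.loc[gid, "m"] / row["delta_p"]
    sup = g.index[(g["true_class"] == "primary") & g["repressor_id"].notna()]
    for gid in sup:
        row = g.loc[gid]
        r0 = out.loc[row["repressor_id"], "p"]
        dm_eff = row["delta_m"] * (1.0 + row["gamma"] * r0)
        out.loc[gid, "m"] = row["alpha0"] / dm_eff
        out.loc[gid, "p"] = row["k_tl"] * out.loc[gid, "m"] / row["delta_p"]
    return out


class _LagTable:
    """Linear-interpolation lookup of staged trajectories with pre-history."""

    def __init__(self, grid: np.ndarray, table: np.ndarray, initial: np.ndarray):
        self.grid = grid
        self.table = table
        self.initial = initial

    def __call__(self, rows: np.ndarray, times: np.ndarray) -> np.ndarray:
        grid = self.grid
        k = np.clip(np.searchsorted(grid, times) - 1, 0, len(grid) - 2)
        w = (times - grid[k]) / (grid[k + 1] - grid[k])
        val = self.table[rows, k] * (1 - w) + self.table[rows, k + 1] * w
        return np.where(times <= grid[0], self.initial[rows], val)


def _solve(rhs, y0, t_start, t_end, grid, context: str):
    try:
        sol = solve_ivp(
            rhs, (t_start, t_end), y0, method="RK45",
            rtol=1e-6, atol=1e-8, dense_output=True,
        )
    except Exception as exc:  # pragma: no cover - integrator internals
        raise RuntimeError(f"ODE integration failed in stage {context}: {exc}") from exc
    if not sol.success:
        raise RuntimeError(f"ODE integration failed in stage {context}: {sol.message}")
    return sol.sol(grid), sol


def simulate_kinetics(spec: CascadeSpec, protocol: StimulusProtocol) -> pd.DataFrame:
    """Noise-free per-gene mRNA at the protocol's sample times.

    Integration is staged in cascade order (kinase closed form, primaries +
    TF proteins, secondaries + repressor proteins, superinduced primaries);
    transcriptional delays are handled by dense interpolation of the
    already-integrated driver trajectory.  All states start at the untreated
    fixed point; with CHX the run starts at t=-0.5 h with translation off.
    """
    spec.validate()
    g = spec.genes
    ss = _steady_state(spec)
    t_start = -CHX_PRETREAT_H if protocol.chx else 0.0
    t_end = max(protocol.sample_times_h)
    if t_end <= t_start:
        t_end = t_start + 1e-3
    grid = np.linspace(t_start, t_end, max(int((t_end - t_start) * 200), 4) + 1)
    sample_t = np.asarray(protocol.sample_times_h)

    e_fun = lambda t: kinase_activity(t, protocol.duration_h, spec.k_act, spec.k_deact)
    ktl_on = 0.0 if protocol.chx else 1.0

    out = pd.DataFrame(0.0, index=g.index, columns=sample_t)

    is_sec = g["true_class"] == "secondary"
    is_sup = (g["true_class"] == "primary") & g["repressor_id"].notna()
    stage_a = g.index[~is_sec & ~is_sup]  # non-superinduced primaries + unresponsive
    stage_b = g.index[is_sec]
    stage_c = g.index[is_sup]

    # --- stage A: kinase-driven genes + their proteins -------------------
    ga = g.loc[stage_a]
    a0, a = ga["alpha0"].to_numpy(), ga["alpha"].to_numpy()
    hn, hk = ga["hill_n"].to_numpy(), ga["hill_k"].to_numpy()
    tau, dm = ga["tau"].to_numpy(), ga["delta_m"].to_numpy()
    ktl = ga["k_tl"].to_numpy() * ktl_on
    dp = ga["delta_p"].to_numpy()
    na = len(ga)
    y0 = np.concatenate([ss.loc[stage_a, "m"], ss.loc[stage_a, "p"]])

    def rhs_a(t, y):
        m, p = y[:na], y[na:]
        drive = a * _hill(e_fun(t - tau), hn, hk)
        return np.concatenate([a0 + drive - dm * m, ktl * m - dp * p])

    traj_a, sol_a = _solve(rhs_a, y0, t_start, t_end, grid, "primary")
    out.loc[stage_a, :] = sol_a.sol(np.clip(sample_t, t_start, t_end))[:na]
    prot_a = _LagTable(grid, traj_a[na:], ss.loc[stage_a, "p"].to_numpy())
    prot_rows = pd.Series(np.arange(na), index=stage_a)

    # --- stage B: secondaries + their proteins ---------------------------
    if len(stage_b):
        gb = g.loc[stage_b]
        b0, b = gb["alpha0"].to_numpy(), gb["alpha"].to_numpy()
        bn, bk = gb["hill_n"].to_numpy(), gb["hill_k"].to_numpy()
        btau, bdm = gb["tau"].to_numpy(), gb["delta_m"].to_numpy()
        bktl = gb["k_tl"].to_numpy() * ktl_on
        bdp = gb["delta_p"].to_numpy()
        drv_rows = prot_rows[gb["driver_id"]].to_numpy()
        nb = len(gb)
        y0 = np.concatenate([ss.loc[stage_b, "m"], ss.loc[stage_b, "p"]])

        def rhs_b(t, y):
            m, p = y[:nb], y[nb:]
            p_drv = prot_a(drv_rows, t - btau)
            drive = b * _hill(p_drv, bn, bk)
            return np.concatenate([b0 + drive - bdm * m, bktl * m - bdp * p])

        traj_b, sol_b = _solve(rhs_b, y0, t_start, t_end, grid, "secondary")
        out.loc[stage_b, :] = sol_b.sol(np.clip(sample_t, t_start, t_end))[:nb]
        rep_table = _LagTable(grid, traj_b[nb:], ss.loc[stage_b, "p"].to_numpy())
        rep_rows = pd.Series(np.arange(nb), index=stage_b)

    # --- stage C: superinduced primaries ---------------------------------
    if len(stage_c):
        gc = g.loc[stage_c]
        c0, c = gc["alpha0"].to_numpy(), gc["alpha"].to_numpy()
        cn, ck = gc["hill_n"].to_numpy(), gc["hill_k"].to_numpy()
        ctau, cdm = gc["tau"].to_numpy(), gc["delta_m"].to_numpy()
        gamma = gc["gamma"].to_numpy()
        rrows = rep_rows[gc["repressor_id"]].to_numpy()
        y0 = ss.loc[stage_c, "m"].to_numpy()

        def rhs_c(t, y):
            drive = c * _hill(e_fun(t - ctau), cn, ck)
            r = rep_table(rrows, np.full(len(rrows), t))
            return c0 + drive - cdm * (1.0 + gamma * r) * y

        _, sol_c = _solve(rhs_c, y0, t_start, t_end, grid, "superinduced")
        out.loc[stage_c, :] = sol_c.sol(np.clip(sample_t, t_start, t_end))

    return out.clip(lower=0.0)


# ---------------------------------------------------------------------------
# measurement


def measure(
    trajectories: pd.DataFrame,
    noise: NoiseModel,
    protocol: StimulusProtocol,
    condition: str,
    stream: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn noise-free trajectories into a log2 expression matrix + sheet.

    y = log2(m * probe_scale) + array_shift + curvature distortion
        + N(0, sigma^2), independently per replicate.  Probe scales depend
    only on ``noise.rng_seed`` so arms measured with the same model share
    them; per-sample draws use ``stream`` to decorrelate arms.
    """
    import warnings

    times = list(protocol.sample_times_h)
    missing = [t for t in times if t not in set(trajectories.columns)]
    if missing:
        raise ValueError(f"trajectories missing sample times: {missing}")
    m = trajectories[times].to_numpy(dtype=float)
    if (m <= 0).any():
        warnings.warn(
            f"{int((m <= 0).sum())} non-positive mRNA values clamped to floor "
            f"{noise.floor} before log2", stacklevel=2,
        )
    m = np.maximum(m, noise.floor)

    scales = noise.probe_scales(trajectories.shape[0])
    rng = np.random.default_rng(np.random.SeedSequence(noise.rng_seed, spawn_key=(stream,)))
    cols, data, rows = [], [], []
    for rep in range(1, protocol.n_replicates + 1):
        for j, t in enumerate(times):
            y = np.log2(m[:, j] * scales)
            shift = rng.normal(0.0, noise.array_shift_sd) if noise.array_shift_sd else 0.0
            curv = rng.normal(0.0, noise.curvature_sd) if noise.curvature_sd else 0.0
            y = y + shift + curv * ((y - 8.0) / 4.0) ** 2
            if noise.sigma:
                y = y + rng.normal(0.0, noise.sigma, size=len(y))
            sid = f"{protocol.experiment_id}:{condition}:t{t:g}:r{rep}"
            cols.append(sid)
            data.append(y)
            rows.append(dict(sample_id=sid, experiment_id=protocol.experiment_id,
                             condition=condition, time_h=float(t), replicate=rep))
    matrix = pd.DataFrame(np.column_stack(data), index=trajectories.index, columns=cols)
    matrix.index.name = "probe_id"
    sheet = pd.DataFrame(rows)
    return matrix, sheet


# ---------------------------------------------------------------------------
# full study


@dataclass
class StudyConfig:
    """Default study conditions: ~600 genes with primary:secondary
    proportions mirroring the real subset (115:48), two biological
    replicates, and the three printed experimental designs."""

    n_primary: int = 90
    n_secondary: int = 38
    n_unresponsive: int = 472
    n_replicates: int = 2
    transient_duration_h: float = 1.0
    sustained_duration_h: float = 14.0
    superinduced_fraction: float = 0.5
    sigma: float = 0.1
    probe_scale_sdlog: float = 0.25
    array_shift_sd: float = 0.3
    curvature_sd: float = 0.05
    k_act: float = 9.0
    k_deact: float = 2.3


def default_protocols(config: StudyConfig | None = None) -> dict[str, dict[str, StimulusProtocol]]:
    """The three experiment designs as {experiment: {condition: protocol}}."""
    cfg = config or StudyConfig()
    n = cfg.n_replicates
    dur_s, dur_t = cfg.sustained_duration_h, cfg.transient_duration_h
    return {
        "duration_series": {
            "untreated": StimulusProtocol(0.0, DURATION_UNTREATED_TIMES, n,
                                          experiment_id="duration_series"),
            "sustained": StimulusProtocol(dur_s, DURATION_SUSTAINED_TIMES, n,
                                          experiment_id="duration_series"),
            "transient": StimulusProtocol(dur_t, DURATION_TRANSIENT_TIMES, n,
                                          experiment_id="duration_series"),
        },
        "sustained_series": {
            "untreated": StimulusProtocol(0.0, SUSTAINED_SERIES_UNTREATED_TIMES, n,
                                          experiment_id="sustained_series"),
            "sustained": StimulusProtocol(dur_s, SUSTAINED_SERIES_TIMES, n,
                                          experiment_id="sustained_series"),
        },
        "chx_series": {
            "untreated": StimulusProtocol(0.0, CHX_SERIES_TIMES, n,
                                          experiment_id="chx_series"),
            "sustained": StimulusProtocol(10.0, CHX_SERIES_TIMES, n,
                                          experiment_id="chx_series"),
            "chx": StimulusProtocol(0.0, CHX_SERIES_TIMES, n, chx=True,
                                    experiment_id="chx_series"),
            "gastrin_chx": StimulusProtocol(10.0, CHX_SERIES_TIMES, n, chx=True,
                                            experiment_id="chx_series"),
        },
    }


def generate_study(seed: int, config: StudyConfig | None = None) -> dict[str, dict]:
    """Simulate the three-experiment study with ground-truth labels.

    Returns {experiment_id: {"matrix": DataFrame, "sheet": DataFrame,
    "truth": DataFrame}}.  The truth table carries ``true_class``,
    ``driver_id`` and ``true_peak_h`` (argmax time of the noise-free
    sustained fold-induction curve on a dense 0-14 h grid; NaN for
    unresponsive genes).  Bit-identical for identical seeds.
    """
    cfg = config or StudyConfig()
    seeds = np.random.SeedSequence(seed).generate_state(8) % (2 ** 31)
    spec = build_default_cascade(
        cfg.n_primary, cfg.n_secondary, cfg.n_unresponsive, seed=int(seeds[0]),
        superinduced_fraction=cfg.superinduced_fraction,
        k_act=cfg.k_act, k_deact=cfg.k_deact,
    )
    protocols = default_protocols(cfg)

    # ground-truth peak time from a dense noise-free sustained run
    dense_times = tuple(np.round(np.arange(0.025, 14.0001, 0.025), 6))
    dense_protocol = StimulusProtocol(14.0, dense_times, 1, experiment_id="duration_series")
    dense = simulate_kinetics(spec, dense_protocol)
    basal = spec.basal_mrna()
    fold = dense.divide(basal, axis=0)
    peak_idx = fold.to_numpy().argmax(axis=1)
    peak_h = np.asarray(dense_times)[peak_idx]
    responsive = spec.genes["true_class"] != "unresponsive"
    truth = pd.DataFrame({
        "gene_id": spec.gene_ids,
        "true_class": spec.genes["true_class"].to_numpy(),
        "driver_id": spec.genes["driver_id"].to_numpy(),
        "true_peak_h": np.where(responsive, peak_h, np.nan),
    }).set_index("gene_id")

    study: dict[str, dict] = {}
    for k, (exp_id, arms) in enumerate(protocols.items()):
        noise = NoiseModel(
            sigma=cfg.sigma, probe_scale_sdlog=cfg.probe_scale_sdlog,
            array_shift_sd=cfg.array_shift_sd, curvature_sd=cfg.curvature_sd,
            rng_seed=int(seeds[k + 1]),
        )
        matrices, sheets = [], []
        for j, (condition, protocol) in enumerate(sorted(arms.items())):
            traj = simulate_kinetics(spec, protocol)
            mat, sheet = measure(traj, noise, protocol, condition, stream=j + 1)
            matrices.append(mat)
            sheets.append(sheet)
        study[exp_id] = {
            "matrix": pd.concat(matrices, axis=1),
            "sheet": pd.concat(sheets, ignore_index=True),
            "truth": truth.copy(),
        }
    study["spec"] = spec  # type: ignore[assignment]
    return study
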