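"""Stochastic 24-state Markov model of thin-filament regulatory units.

The thin filament is modeled as ``n_units`` (default 26) regulatory units in
series.  Each unit occupies one of 24 states, the product of four factors:

* TnC calcium site: free / bound            (rates kCa+ * [Ca], kCa-)
* TnI switch peptide: unbound / bound       (kSP+, kSP-; the on-rate is
  multiplied by ``lambda`` when calcium is not bound)
* TnI inhibitory peptide: actin-bound / released
  (kIP+, kIP-; release requires the switch peptide bound and tropomyosin out
  of the blocked position)
* tropomyosin azimuthal position: B (blocked) / C (closed) / M (myosin bound)

Only one factor may change per transition.  Tropomyosin may enter B only
while the inhibitory peptide is actin-bound, and M is reachable only from C;
strong myosin binding (C -> M) additionally requires the inhibitory peptide
released, since the inhibitory peptide occupies the actin surface myosin
needs, and conversely bound myosin occludes that site so the inhibitory
peptide cannot re-attach until the unit returns to C.  Activation is
therefore throttled by blocked-state occupancy: the inhibitory peptide can
only release while tropomyosin is out of B, so K_BC and the chain strain set
how often a unit presents a myosin-ready site; deactivation requires myosin
detachment before the unit can re-lock into B.

Nearest-neighbor cooperativity enters through the tropomyosin chain: the
three positions map to azimuthal angles x_C = 0, x_B = -eta*theta_B and
x_M = +mu*theta_M, where the base angles theta_B and theta_M are fixed so
that at the published eta = mu = 9 the blocked and myosin positions sit at
the structural azimuthal shifts of roughly -25 and +10 degrees from closed
(the B-to-C excursion of tropomyosin on actin is much larger than the
C-to-M one).  A unit at position x with neighbors at x_l, x_r carries
elastic energy (gamma/2)[(x-x_l)^2+(x-x_r)^2].
B<->C transitions use a thermodynamically split form

    rate(B->C) = k_ref_bc * K_BC^d  * exp(-d * dE)
    rate(C->B) = k_ref_bc * K_BC^(d-1) * exp((1-d) * dE)

with d = ``delta_split`` and dE the chain-energy change (in units of RT) of
the move given the neighbors' current positions, so the pair equilibrium is
exactly K_BC * exp(-dE).  C<->M uses the same split around the kMD+/kMD-
pair.  End units have one neighbor; the missing neighbor contributes no
strain (free ends).  Force is the number of units in the M position.

The integrator is fixed-step kinetic Monte Carlo (per-step transition
probability rate*dt, with a guard max total exit rate * dt <= 0.1), chosen
over event-driven simulation because the twitch protocol has time-varying
calcium.  An exact single-unit stationary distribution (linear algebra on the
24-state generator) serves as the independent oracle for the sampler.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ModelParameters",
    "CalciumProtocol",
    "FilamentTrajectory",
    "ReducibleMatrixError",
    "N_STATES",
    "state_index",
    "state_tuple",
    "build_rate_matrix",
    "stationary_distribution_single_unit",
    "max_total_exit_rate",
    "auto_dt",
    "simulate_filament",
    "steady_state_force",
    "force_pca_curve",
    "simulate_twitch",
    "occupancy_single_unit",
    "pca_to_uM",
    "write_trajectory",
    "read_trajectory",
]

N_STATES = 24
TM_B, TM_C, TM_M = 0, 1, 2
TM_NONE = 3  # missing neighbor (chain end)

R_GAS = 8.314462618e-3  # kJ/mol/K

DEFAULT_DT = 2e-5  # s
DT_GUARD = 0.1  # max total exit rate * dt


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Rate and coupling constants of the regulatory-unit model.

    Rates in 1/s except ``k_ca_on`` (1/(uM s)); ``gamma`` in kJ/mol/rad^2;
    ``base_angle_b_deg`` and ``base_angle_m_deg`` (degrees) are scaled by the
    dimensionless eta and mu to place the blocked and myosin-bound azimuthal
    positions relative to closed.
    """

    k_ca_on: float = 350.0
    k_ca_off: float = 1000.0
    k_sp_on: float = 180.0
    k_sp_off: float = 300.0
    k_ip_on: float = 620.0
    k_ip_off: float = 225.0
    k_md_on: float = 550.0
    k_md_off: float = 225.0
    k_ref_bc: float = 675.0
    kbc: float = 0.76
    f_xy: float = 225.0
    delta_split: float = 0.48
    lambda_coupling: float = 0.008
    eta: float = 9.0
    mu: float = 9.0
    gamma: float = 60.0
    n_units: int = 26
    temperature: float = 300.0
    base_angle_b_deg: float = 25.0 / 9.0
    base_angle_m_deg: float = 10.0 / 9.0

    def __post_init__(self):
        rates = (
            "k_ca_on k_ca_off k_sp_on k_sp_off k_ip_on k_ip_off "
            "k_md_on k_md_off k_ref_bc f_xy"
        ).split()
        for name in rates:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kbc <= 0:
            raise ValueError("kbc must be positive")
        if not 0.0 <= self.delta_split <= 1.0:
            raise ValueError("delta_split must be in [0, 1]")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.gamma < 0 or self.temperature <= 0:
            raise ValueError("gamma must be >= 0 and temperature positive")

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)

    # -- presets ------------------------------------------------------------

    @classmethod
    def preset(cls, name: str) -> "ModelParameters":
        """Shipped parameter sets: wt, s215l, gamma_only, kbc_only.

        ``gamma_only`` and ``kbc_only`` apply one of the two mutation effects
        in isolation for the factorial decomposition of the mutant phenotype.
        """
        presets = {
            "wt": dict(gamma=60.0, kbc=0.76),
            "s215l": dict(gamma=31.6, kbc=0.97),
            "gamma_only": dict(gamma=31.6, kbc=0.76),
            "kbc_only": dict(gamma=60.0, kbc=0.97),
        }
        try:
            return cls(**presets[name])
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; choose from {sorted(presets)}"
            ) from None

    # -- YAML round trip with published symbol aliases ----------------------

    _ALIASES = {
        "kCa+": "k_ca_on",
        "kCa-": "k_ca_off",
        "kSP+": "k_sp_on",
        "kSP-": "k_sp_off",
        "kIP+": "k_ip_on",
        "kIP-": "k_ip_off",
        "kMD+": "k_md_on",
        "kMD-": "k_md_off",
        "krefBC": "k_ref_bc",
        "K_BC": "kbc",
        "f_XY": "f_xy",
        "delta": "delta_split",
        "lambda": "lambda_coupling",
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, value in raw.items():
            kwargs[cls._ALIASES.get(key, key)] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# State enumeration
# ---------------------------------------------------------------------------

def state_index(ca: int, sp: int, ip: int, tm: int) -> int:
    """Bijective index of (TnC-Ca, TnI-SP, TnI-IP, Tm-position)."""
    if ca not in (0, 1) or sp not in (0, 1) or ip not in (0, 1) or tm not in (0, 1, 2):
        raise ValueError("invalid factor values")
    return ((ca * 2 + sp) * 2 + ip) * 3 + tm


def state_tuple(idx: int) -> tuple[int, int, int, int]:
    if not 0 <= idx < N_STATES:
        raise ValueError(f"state index out of range: {idx}")
    tm = idx % 3
    ip = (idx // 3) % 2
    sp = (idx // 6) % 2
    ca = idx // 12
    return ca, sp, ip, tm


_CA_OF = np.array([state_tuple(i)[0] for i in range(N_STATES)], dtype=np.int64)
_SP_OF = np.array([state_tuple(i)[1] for i in range(N_STATES)], dtype=np.int64)
_IP_OF = np.array([state_tuple(i)[2] for i in range(N_STATES)], dtype=np.int64)
_TM_OF = np.array([state_tuple(i)[3] for i in range(N_STATES)], dtype=np.int64)

#: The fully relaxed start state: Ca free, SP unbound, IP actin-bound, Tm in B.
RELAXED_STATE = state_index(0, 0, 0, TM_B)


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def _tm_angles(params: ModelParameters) -> np.ndarray:
    """Azimuthal angles (radians) of the B, C, M tropomyosin positions."""
    return np.array(
        [
            -params.eta * np.radians(params.base_angle_b_deg),
            0.0,
            params.mu * np.radians(params.base_angle_m_deg),
        ]
    )


def _strain_rt(params: ModelParameters, pos: int, left: int, right: int) -> float:
    """Chain elastic energy (units of RT) of a unit at ``pos`` given neighbors.

    ``left``/``right`` are tropomyosin position codes, TM_NONE for a free end.
    """
    x = _tm_angles(params)
    rt = R_GAS * params.temperature
    e = 0.0
    for nb in (left, right):
        if nb != TM_NONE:
            e += 0.5 * params.gamma * (x[pos] - x[nb]) ** 2
    return e / rt


def _tm_rates(
    params: ModelParameters, ip: int, tm_from: int, tm_to: int, left: int, right: int
) -> float:
    """Strain-coupled tropomyosin transition rate for one neighbor context."""
    d = params.delta_split
    if {tm_from, tm_to} == {TM_B, TM_C}:
        de = _strain_rt(params, TM_C, left, right) - _strain_rt(params, TM_B, left, right)
        if tm_from == TM_B:
            if ip == 0:
                return params.k_ref_bc * params.kbc**d * np.exp(-d * de)
            # escape from the structurally forbidden (B, IP released) corner
            return params.f_xy * np.exp(-d * de)
        if ip == 1:
            return 0.0  # B is off-limits while the inhibitory peptide is off actin
        return params.k_ref_bc * params.kbc ** (d - 1.0) * np.exp((1.0 - d) * de)
    if {tm_from, tm_to} == {TM_C, TM_M}:
        de = _strain_rt(params, TM_M, left, right) - _strain_rt(params, TM_C, left, right)
        if tm_from == TM_C:
            if ip == 0:
                return 0.0  # actin-bound inhibitory peptide excludes myosin
            return params.k_md_on * np.exp(-d * de)
        return params.k_md_off * np.exp((1.0 - d) * de)
    return 0.0  # direct B<->M moves are forbidden


def _factor_rates(params: ModelParameters, ca: float, idx: int) -> list[tuple[int, float]]:
    """Non-tropomyosin transitions (target, rate) out of state ``idx``."""
    ca_b, sp, ip, tm = state_tuple(idx)
    out = []
    if ca_b == 0:
        out.append((idx + 12, params.k_ca_on * ca))
    else:
        out.append((idx - 12, params.k_ca_off))
    if sp == 0:
        rate = params.k_sp_on if ca_b == 1 else params.lambda_coupling * params.k_sp_on
        out.append((idx + 6, rate))
    else:
        out.append((idx - 6, params.k_sp_off))
    if ip == 0:
        rate = params.k_ip_on if (sp == 1 and tm != TM_B) else 0.0
        out.append((idx + 3, rate))
    else:
        # bound myosin occludes the inhibitory peptide's actin site
        out.append((idx - 3, params.k_ip_off if tm != TM_M else 0.0))
    return out


def build_rate_matrix(
    params: ModelParameters,
    ca: float,
    neighbor_context: tuple[int | None, int | None] = (None, None),
) -> np.ndarray:
    """24x24 generator at calcium ``ca`` (uM) for a fixed neighbor context.

    ``neighbor_context`` holds the tropomyosin position codes (0/1/2 or
    ``None`` for a free end) of the left and right neighbors.  Rows sum to
    zero; off-diagonal entries are the transition rates.
    """
    if ca < 0:
        raise ValueError("ca must be >= 0")
    left = TM_NONE if neighbor_context[0] is None else int(neighbor_context[0])
    right = TM_NONE if neighbor_context[1] is None else int(neighbor_context[1])
    q = np.zeros((N_STATES, N_STATES))
    for s in range(N_STATES):
        for t, rate in _factor_rates(params, ca, s):
            q[s, t] = rate
        _, _, ip, tm = state_tuple(s)
        for tm_to in (TM_B, TM_C, TM_M):
            if tm_to == tm:
                continue
            rate = _tm_rates(params, ip, tm, tm_to, left, right)
            if rate > 0:
                q[s, s - tm + tm_to] = rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


class ReducibleMatrixError(ValueError):
    """Raised when the generator has more than one closed communicating class."""

    def __init__(self, classes):
        self.classes = classes
        super().__init__(f"reducible generator: closed classes {classes}")


def stationary_distribution_single_unit(params: ModelParameters, ca: float) -> np.ndarray:
    """Exact stationary distribution of one neighbor-free unit.

    States that are transient by construction (the blocked position with the
    inhibitory peptide released) receive probability zero.  If the generator
    has several closed communicating classes the stationary law is not unique
    and a :class:`ReducibleMatrixError` listing them is raised.
    """
    q = build_rate_matrix(params, ca)
    adj = csr_matrix((q > 0).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    closed = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        outside = np.setdiff1d(np.arange(N_STATES), members)
        if len(outside) == 0 or not np.any(q[np.ix_(members, outside)] > 0):
            closed.append(members.tolist())
    if len(closed) != 1:
        raise ReducibleMatrixError(closed)
    members = np.array(closed[0])
    qr = q[np.ix_(members, members)]
    n = len(members)
    a = np.vstack([qr.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi_r, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.zeros(N_STATES)
    pi[members] = np.clip(pi_r, 0.0, None)
    pi /= pi.sum()
    return pi


# ---------------------------------------------------------------------------
# Kernel transition tables
# ---------------------------------------------------------------------------

def _transition_tables(params: ModelParameters):
    """Precomputed per-state transition tables for the Monte-Carlo kernel."""
    caon_target = np.full(N_STATES, -1, dtype=np.int64)
    const_rate = np.zeros((N_STATES, 4))
    const_target = np.zeros((N_STATES, 4), dtype=np.int64)
    const_n = np.zeros(N_STATES, dtype=np.int64)
    tm_rate = np.zeros((N_STATES, 4, 4, 2))
    tm_target = np.zeros((N_STATES, 2), dtype=np.int64)
    tm_n = np.zeros(N_STATES, dtype=np.int64)

    for s in range(N_STATES):
        ca_b, sp, ip, tm = state_tuple(s)
        k = 0
        for t, rate in _factor_rates(params, 1.0, s):
            if t == s + 12 and ca_b == 0:
                caon_target[s] = t  # rate is k_ca_on * [Ca], handled in-kernel
                continue
            if rate > 0:
                const_rate[s, k] = rate
                const_target[s, k] = t
                k += 1
        const_n[s] = k
        k = 0
        for tm_to in (TM_B, TM_C, TM_M):
            if tm_to == tm:
                continue
            rates = np.zeros((4, 4))
            for left in range(4):
                for right in range(4):
                    rates[left, right] = _tm_rates(params, ip, tm, tm_to, left, right)
            if np.any(rates > 0):
                tm_rate[s, :, :, k] = rates
                tm_target[s, k] = s - tm + tm_to
                k += 1
        tm_n[s] = k
    return caon_target, const_n, const_rate, const_target, tm_n, tm_rate, tm_target


def max_total_exit_rate(params: ModelParameters, ca_max: float) -> tuple[float, str]:
    """Worst-case total exit rate over states and neighbor contexts.

    Returns the bound and the name of its largest single contribution, used
    for the time-step guard and its error message.
    """
    caon_target, const_n, const_rate, _, tm_n, tm_rate, _ = _transition_tables(params)
    best, label = 0.0, ""
    for s in range(N_STATES):
        total = const_rate[s, : const_n[s]].sum()
        parts = {"constant factor rates": const_rate[s, : const_n[s]].sum() or 0.0}
        if caon_target[s] >= 0:
            r = params.k_ca_on * ca_max
            total += r
            parts["k_ca_on * ca"] = r
        for k in range(tm_n[s]):
            r = tm_rate[s, :, :, k].max()
            total += r
            parts["tropomyosin (strain-coupled)"] = max(
                parts.get("tropomyosin (strain-coupled)", 0.0), r
            )
        if total > best:
            best = total
            label = max(parts, key=parts.get)
    return best, label


def auto_dt(params: ModelParameters, ca_max: float, dt_max: float = DEFAULT_DT) -> float:
    """Largest dt <= ``dt_max`` satisfying the exit-rate guard with margin."""
    bound, _ = max_total_exit_rate(params, ca_max)
    return float(min(dt_max, 0.95 * DT_GUARD / bound))


# ---------------------------------------------------------------------------
# Monte-Carlo kernels (numba)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _kmc_kernel(
    n_traj,
    n_units,
    n_steps,
    dt,
    ca_arr,
    seed,
    caon_target,
    k_ca_on,
    const_n,
    const_rate,
    const_target,
    tm_n,
    tm_rate,
    tm_target,
    tm_of,
    p_up,
    init_state,
    record_stride,
    force_acc,
):
    np.random.seed(seed)
    state = np.empty(n_units, np.int64)
    for _tr in range(n_traj):
        for i in range(n_units):
            state[i] = init_state
        rec = 0
        for step in range(n_steps):
            if step % record_stride == 0:
                m = 0
                for i in range(n_units):
                    if tm_of[state[i]] == 2:
                        m += 1
                force_acc[rec] += m
                rec += 1
            ca = ca_arr[step]
            for i in range(n_units):
                s = state[i]
                u = np.random.random()
                if u >= p_up[s]:
                    continue
                p = 0.0
                t = caon_target[s]
                if t >= 0:
                    p += k_ca_on * ca * dt
                    if u < p:
                        state[i] = t
                        continue
                fired = False
                for k in range(const_n[s]):
                    p += const_rate[s, k] * dt
                    if u < p:
                        state[i] = const_target[s, k]
                        fired = True
                        break
                if fired:
                    continue
                if tm_n[s] > 0:
                    left = tm_of[state[i - 1]] if i > 0 else 3
                    right = tm_of[state[i + 1]] if i < n_units - 1 else 3
                    for k in range(tm_n[s]):
                        p += tm_rate[s, left, right, k] * dt
                        if u < p:
                            state[i] = tm_target[s, k]
                            break


@njit(cache=False)
def _occupancy_kernel(
    n_traj,
    n_steps,
    burn_steps,
    dt,
    ca,
    seed,
    caon_target,
    k_ca_on,
    const_n,
    const_rate,
    const_target,
    tm_n,
    tm_rate,
    tm_target,
    p_up,
    init_state,
    occ_acc,
):
    np.random.seed(seed)
    for _tr in range(n_traj):
        s = init_state
        for step in range(n_steps):
            if step >= burn_steps:
                occ_acc[s] += 1.0
            u = np.random.random()
            if u >= p_up[s]:
                continue
            p = 0.0
            t = caon_target[s]
            if t >= 0:
                p += k_ca_on * ca * dt
                if u < p:
                    s = t
                    continue
            fired = False
            for k in range(const_n[s]):
                p += const_rate[s, k] * dt
                if u < p:
                    s = const_target[s, k]
                    fired = True
                    break
            if fired:
                continue
            for k in range(tm_n[s]):
                p += tm_rate[s, 3, 3, k] * dt  # neighbor-free context
                if u < p:
                    s = tm_target[s, k]
                    break


# ---------------------------------------------------------------------------
# Protocols and trajectories
# ---------------------------------------------------------------------------

def pca_to_uM(pca: float) -> float:
    """Free calcium in uM from pCa (= -log10 [Ca] in M)."""
    return 10.0 ** (6.0 - pca)


@dataclass(frozen=True)
class CalciumProtocol:
    """Constant calcium bath or a diastolic-to-peak calcium transient.

    The transient is a difference of exponentials, normalized so that the
    concentration rises from ``diastolic`` (uM) to exactly ``peak`` (uM)
    after ``stimulus_time`` and decays back.  Defaults: 0.1 uM diastolic,
    1 uM peak, 20 ms rise and 150 ms decay time constants.
    """

    mode: str = "constant"
    constant_ca: float = 0.1
    diastolic: float = 0.1
    peak: float = 1.0
    tau_rise: float = 0.020
    tau_decay: float = 0.150
    stimulus_time: float = 0.0

    def __post_init__(self):
        if self.mode not in ("constant", "transient"):
            raise ValueError(f"mode must be 'constant' or 'transient', got {self.mode!r}")
        if self.constant_ca <= 0 or self.diastolic <= 0:
            raise ValueError("calcium concentrations must be positive")
        if self.mode == "transient" and self.peak < self.diastolic:
            raise ValueError("transient peak must be >= diastolic level")
        if self.tau_rise <= 0 or self.tau_decay <= 0 or self.tau_rise >= self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")

    def ca_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.mode == "constant":
            return np.full_like(t, self.constant_ca)
        u = t - self.stimulus_time
        shape = np.where(
            u > 0, np.exp(-np.clip(u, 0, None) / self.tau_decay)
            - np.exp(-np.clip(u, 0, None) / self.tau_rise), 0.0
        )
        u_peak = (
            np.log(self.tau_decay / self.tau_rise)
            * self.tau_rise * self.tau_decay / (self.tau_decay - self.tau_rise)
        )
        g_max = np.exp(-u_peak / self.tau_decay) - np.exp(-u_peak / self.tau_rise)
        return self.diastolic + (self.peak - self.diastolic) * shape / g_max

    @property
    def max_ca(self) -> float:
        return self.constant_ca if self.mode == "constant" else max(self.peak, self.diastolic)


@dataclass(frozen=True)
class FilamentTrajectory:
    """Ensemble-mean force (M-state unit count) on a time grid."""

    time: np.ndarray
    force: np.ndarray
    n_trajectories: int
    seed: int
    n_units: int
    stimulus_time: float | None = None

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        force = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "force", force)
        if time.shape != force.shape:
            raise ValueError("time and force must have matching shapes")
        if np.any(np.diff(time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(force < 0) or np.any(force > self.n_units):
            raise ValueError("force must lie in [0, n_units]")


def _run_kernel(params, ca_arr, dt, n_traj, seed, record_stride):
    (caon_target, const_n, const_rate, const_target, tm_n, tm_rate, tm_target) = (
        _transition_tables(params)
    )
    ca_max = float(ca_arr.max())
    p_up = np.zeros(N_STATES)
    for s in range(N_STATES):
        p = const_rate[s, : const_n[s]].sum()
        if caon_target[s] >= 0:
            p += params.k_ca_on * ca_max
        for k in range(tm_n[s]):
            p += tm_rate[s, :, :, k].max()
        p_up[s] = p * dt
    n_steps = len(ca_arr)
    n_rec = (n_steps + record_stride - 1) // record_stride
    force_acc = np.zeros(n_rec)
    _kmc_kernel(
        n_traj,
        params.n_units,
        n_steps,
        dt,
        ca_arr,
        seed,
        caon_target,
        params.k_ca_on,
        const_n,
        const_rate,
        const_target,
        tm_n,
        tm_rate,
        tm_target,
        _TM_OF,
        p_up,
        RELAXED_STATE,
        record_stride,
        force_acc,
    )
    return force_acc / n_traj


def simulate_filament(
    params: ModelParameters,
    protocol: CalciumProtocol,
    duration: float,
    dt: float | None = None,
    n_trajectories: int = 1920,
    seed: int = 0,
    record_stride: int | None = None,
) -> FilamentTrajectory:
    """Fixed-step kinetic Monte Carlo of the coupled regulatory-unit chain.

    Raises if ``dt`` violates the stability guard (max total exit rate times
    dt must not exceed 0.1); with ``dt=None`` a compliant step is chosen
    automatically.
    """
    if n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    if dt is None:
        dt = auto_dt(params, protocol.max_ca)
    bound, worst = max_total_exit_rate(params, protocol.max_ca)
    if bound * dt > DT_GUARD:
        raise ValueError(
            f"dt guard violated: total exit rate bound {bound:.1f}/s (dominated by "
            f"{worst}) times dt={dt:g} exceeds {DT_GUARD}"
        )
    if record_stride is None:
        record_stride = max(1, int(round(5e-4 / dt)))
    n_steps = int(round(duration / dt))
    t_steps = np.arange(n_steps) * dt
    ca_arr = np.ascontiguousarray(protocol.ca_at(t_steps))
    force = _run_kernel(params, ca_arr, dt, n_trajectories, int(seed), record_stride)
    time = t_steps[::record_stride][: len(force)]
    return FilamentTrajectory(
        time=time,
        force=force,
        n_trajectories=n_trajectories,
        seed=int(seed),
        n_units=params.n_units,
        stimulus_time=protocol.stimulus_time if protocol.mode == "transient" else None,
    )


def steady_state_force(
    params: ModelParameters,
    pca: float,
    n_trajectories: int = 1920,
    seed: int = 0,
    duration: float = 5.0,
    dt: float | None = None,
) -> float:
    """Mean force over the final 25% of a constant-calcium interval.

    The default 5 s interval lets the chain reach steady state before the
    averaging window opens.
    """
    protocol = CalciumProtocol(mode="constant", constant_ca=pca_to_uM(pca))
    traj = simulate_filament(
        params, protocol, duration=duration, dt=dt, n_trajectories=n_trajectories, seed=seed
    )
    window = traj.time >= 0.75 * duration
    return float(traj.force[window].mean())


def force_pca_curve(
    params: ModelParameters,
    pcas,
    n_trajectories: int = 1920,
    seed: int = 0,
    duration: float = 5.0,
) -> np.ndarray:
    """Steady-state force at each pCa (seeds derived per point)."""
    return np.array(
        [
            steady_state_force(
                params, pca, n_trajectories=n_trajectories,
                seed=(int(seed) + 7919 * k) % 2**31, duration=duration,
            )
            for k, pca in enumerate(pcas)
        ]
    )


def simulate_twitch(
    params: ModelParameters,
    protocol: CalciumProtocol | None = None,
    n_trajectories: int = 1920,
    n_repeats: int = 10,
    seed: int = 0,
    equilibration: float = 1.5,
    post_duration: float = 2.5,
    baseline_window: float = 0.25,
) -> FilamentTrajectory:
    """Averaged twitch: equilibrate at diastolic calcium, then fire a transient.

    Each repeat is an independent ``n_trajectories`` ensemble mean; repeats
    are averaged (matching the convention of running several stochastic
    twitch simulations and averaging).  The returned trajectory starts
    ``baseline_window`` seconds before the stimulus so twitch metrics can
    measure the diastolic baseline.
    """
    if protocol is None:
        protocol = CalciumProtocol(mode="transient", stimulus_time=equilibration)
    elif protocol.mode != "transient":
        raise ValueError("twitch simulation needs a transient calcium protocol")
    else:
        protocol = dataclasses.replace(protocol, stimulus_time=equilibration)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    duration = equilibration + post_duration
    traces = []
    time = None
    for r in range(n_repeats):
        traj = simulate_filament(
            params,
            protocol,
            duration=duration,
            n_trajectories=n_trajectories,
            seed=(int(seed) + 104729 * r) % 2**31,
        )
        traces.append(traj.force)
        time = traj.time
    force = np.mean(traces, axis=0)
    keep = time >= equilibration - baseline_window
    return FilamentTrajectory(
        time=time[keep],
        force=force[keep],
        n_trajectories=n_trajectories * n_repeats,
        seed=int(seed),
        n_units=params.n_units,
        stimulus_time=equilibration,
    )


def occupancy_single_unit(
    params: ModelParameters,
    ca: float,
    n_steps: int = 100_000,
    n_trajectories: int = 64,
    seed: int = 0,
    dt: float | None = None,
    burn_fraction: float = 0.2,
) -> np.ndarray:
    """Monte-Carlo state-occupancy frequencies of one neighbor-free unit.

    Time-averaged over ``n_steps`` per trajectory after a burn-in, for direct
    comparison with :func:`stationary_distribution_single_unit`.
    """
    p = params.replace(n_units=1)
    if dt is None:
        dt = auto_dt(p, ca)
    bound, worst = max_total_exit_rate(p, ca)
    if bound * dt > DT_GUARD:
        raise ValueError(
            f"dt guard violated: exit-rate bound {bound:.1f}/s (dominated by {worst})"
        )
    (caon_target, const_n, const_rate, const_target, tm_n, tm_rate, tm_target) = (
        _transition_tables(p)
    )
    p_up = np.zeros(N_STATES)
    for s in range(N_STATES):
        tot = const_rate[s, : const_n[s]].sum()
        if caon_target[s] >= 0:
            tot += p.k_ca_on * ca
        for k in range(tm_n[s]):
            tot += tm_rate[s, 3, 3, k]
        p_up[s] = tot * dt
    burn = int(burn_fraction * n_steps)
    occ = np.zeros(N_STATES)
    _occupancy_kernel(
        n_trajectories,
        n_steps + burn,
        burn,
        dt,
        float(ca),
        int(seed),
        caon_target,
        p.k_ca_on,
        const_n,
        const_rate,
        const_target,
        tm_n,
        tm_rate,
        tm_target,
        p_up,
        RELAXED_STATE,
        occ,
    )
    return occ / occ.sum()


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def write_trajectory(traj: FilamentTrajectory, path: str | Path) -> None:
    """Two-column text (time_s, mean_force) with a metadata header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# n_trajectories={traj.n_trajectories} seed={traj.seed} "
            f"n_units={traj.n_units} stimulus_time={traj.stimulus_time}\n"
        )
        fh.write("# time_s\tmean_force\n")
        for t, f in zip(traj.time, traj.force):
            fh.write(f"{t:.8g}\t{f:.8g}\n")


def read_trajectory(path: str | Path) -> FilamentTrajectory:
    path = Path(path)
    meta = {}
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            continue
        t, f = line.split()
        rows.append((float(t), float(f)))
    arr = np.array(rows)
    stim = meta.get("stimulus_time", "None")
    return FilamentTrajectory(
        time=arr[:, 0],
        force=arr[:, 1],
        n_trajectories=int(meta.get("n_trajectories", 1)),
        seed=int(meta.get("seed", 0)),
        n_units=int(meta.get("n_units", 26)),
        stimulus_time=None if stim == "None" else float(stim),
    )
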