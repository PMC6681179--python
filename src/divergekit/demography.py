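"""Two-population divergence models on the joint SFS.

A scenario family built from six divergence categories — strict isolation
(SI), isolation with migration (IM), ancient migration with one (AM) or two
(PAM) contact episodes, and secondary contact with one (SC) or two (PSC)
contact episodes — optionally combined with exponential growth (``ex``
suffix), a background-selection locus-class mixture (``2N``: a fraction ``nr``
of loci evolves with all effective sizes multiplied by ``bf``), and a
migration-heterogeneity mixture (``2M2P``: fractions ``P1``/``P2`` of loci
receive no migration into population 1/2).  Excluding the combinations SI
cannot express, the catalogue holds 34 scenarios.

All parameters are scaled by a reference (ancestral) population size
``Nref``: sizes ``nu = N/Nref``, times in units of ``2*Nref`` generations,
migration ``M = 2*Nref*m`` with ``M12`` the rate *into* population 1.  ``O``
is the probability a site's ancestral allele was correctly inferred; the
mis-polarization transform mixes the expected spectrum with its
derived/ancestral-reversed image.

The expected joint SFS is computed either by an exact integration of the
two-population coalescent Markov chain over lineage-count configurations
(practical up to roughly n1 + n2 = 12 allele copies) or by a Monte-Carlo
coalescent engine (msprime branch-length spectra averaged over independent
replicates).  Fitting maximizes a Poisson composite likelihood with the
overall scale profiled analytically, from multiple log-uniform starts, by
derivative-free local search; models are compared by AIC and uncertainties
come from refitting bootstrap spectra.
"""

from __future__ import annotations

import functools
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import spsolve
from scipy.special import expit, gammaln, logit

from .spectra import JointSFS

logger = logging.getLogger(__name__)

CATEGORIES = ("SI", "IM", "AM", "PAM", "SC", "PSC")
FLAGS = ("ex", "2N", "2M2P")

#: maximum total haploid sample size handled by the exact engine
EXACT_ENGINE_MAX = 12


class ModelError(ValueError):
    pass


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

def param_names(category: str, flags=()) -> list:
    """Ordered free-parameter names for a scenario (including ``O``)."""
    if category not in CATEGORIES:
        raise ModelError(f"unknown category {category!r}")
    flags = frozenset(flags)
    if "2N" in flags and "2M2P" in flags:
        raise ModelError("2N and 2M2P cannot be combined")
    if category == "SI" and "2M2P" in flags:
        raise ModelError("SI has no migration; 2M2P is not expressible")
    names = ["nu1", "nu2"]
    if category != "SI":
        names += ["M12", "M21"]
    if category in ("SI", "AM", "PAM", "SC", "PSC"):
        names += ["t_iso"]
    if category != "SI":
        names += ["t_sc"]
    if "ex" in flags:
        names += ["nu_a1", "nu_a2", "t_scg"]
    if "2M2P" in flags:
        names += ["P1", "P2"]
    if "2N" in flags:
        names += ["nr", "bf"]
    names += ["O"]
    return names


def model_name(category: str, flags=()) -> str:
    flags = frozenset(flags)
    name = category
    if "2N" in flags:
        name += "2N"
    if "2M2P" in flags:
        name += "2M2P"
    if "ex" in flags:
        name += "ex"
    return name


def parse_model_name(name: str):
    """Parse a catalogue name like ``PSC2M2Pex`` into (category, flags)."""
    flags = set()
    if name.endswith("ex"):
        flags.add("ex")
        name = name[:-2]
    if name.endswith("2M2P"):
        flags.add("2M2P")
        name = name[:-4]
    elif name.endswith("2N"):
        flags.add("2N")
        name = name[:-2]
    if name not in CATEGORIES:
        raise ModelError(f"cannot parse model name {name!r}")
    return name, frozenset(flags)


def model_catalogue() -> list:
    """The 34-scenario catalogue: categories x {,ex} x {,2N,2M2P} minus SI x 2M2P."""
    names = []
    for cat in CATEGORIES:
        for het in (frozenset(), frozenset({"2N"}), frozenset({"2M2P"})):
            for growth in (frozenset(), frozenset({"ex"})):
                flags = het | growth
                if cat == "SI" and "2M2P" in flags:
                    continue
                names.append(model_name(cat, flags))
    return names


@dataclass
class DemographicModel:
    """A scenario category + flags + named scaled parameters."""

    category: str
    flags: frozenset = frozenset()
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.flags = frozenset(self.flags)

    @classmethod
    def from_name(cls, name: str, params=None) -> "DemographicModel":
        cat, flags = parse_model_name(name)
        return cls(cat, flags, dict(params or {}))

    @property
    def name(self) -> str:
        return model_name(self.category, self.flags)

    def param_names(self) -> list:
        return param_names(self.category, self.flags)

    def validate(self) -> None:
        missing = [p for p in self.param_names() if p not in self.params and p != "O"]
        if missing:
            raise ModelError(f"{self.name}: missing parameters {missing}")
        p = self.params
        for name in p:
            if name.startswith("nu") and p[name] <= 0:
                raise ModelError(f"size {name} must be positive")
            if name.startswith("t_") and p[name] < 0:
                raise ModelError(f"time {name} must be non-negative")
            if name.startswith("M") and p[name] < 0:
                raise ModelError(f"migration {name} must be non-negative")
        if "2M2P" in self.flags:
            if not (0 <= p["P1"] and 0 <= p["P2"] and p["P1"] + p["P2"] <= 1):
                raise ModelError("require P1, P2 >= 0 and P1 + P2 <= 1")
        if "2N" in self.flags:
            if not (0 <= p["nr"] <= 1 and 0 < p["bf"] <= 1):
                raise ModelError("require nr in [0,1] and bf in (0,1]")
        if "O" in p and not (0.5 < p["O"] <= 1):
            raise ModelError("O must lie in (0.5, 1]")


# ---------------------------------------------------------------------------
# Epoch schedules
# ---------------------------------------------------------------------------

@dataclass
class Epoch:
    """One epoch, forward in time.  Sizes may differ at the two ends
    (exponential trajectory); constant when equal."""

    duration: float
    nu1_start: float
    nu1_end: float
    nu2_start: float
    nu2_end: float
    m12: float
    m21: float

    @property
    def is_exponential(self) -> bool:
        return self.nu1_start != self.nu1_end or self.nu2_start != self.nu2_end


@dataclass
class EpochSchedule:
    """Epochs ordered from the population split to the present, plus the
    ancestral (pre-split) population size."""

    epochs: list
    nu_anc: float = 1.0

    @property
    def total_time(self) -> float:
        return sum(e.duration for e in self.epochs)


def build_epochs(model: DemographicModel) -> EpochSchedule:
    """Expand a scenario into its forward epoch schedule.

    Contact patterns (forward from the split): SI — isolation throughout;
    IM — migration throughout; AM — contact then isolation ending at the
    present; PAM — contact/isolation alternated twice; SC — isolation then
    contact ending at the present; PSC — the SC pattern repeated twice, each
    episode at half length.  With the ``ex`` flag the post-split sizes are
    (nu_a1, nu_a2) and an extra epoch of length ``t_scg`` is appended in
    which sizes run exponentially to (nu1, nu2); its migration state matches
    the category's present state (on for IM/SC/PSC, off for SI/AM/PAM).
    """
    model.validate()
    p = model.params
    cat = model.category
    m12 = p.get("M12", 0.0)
    m21 = p.get("M21", 0.0)

    if cat == "SI":
        pattern = [(p["t_iso"], False)]
    elif cat == "IM":
        pattern = [(p["t_sc"], True)]
    elif cat == "AM":
        pattern = [(p["t_sc"], True), (p["t_iso"], False)]
    elif cat == "PAM":
        pattern = [(p["t_sc"] / 2, True), (p["t_iso"] / 2, False)] * 2
    elif cat == "SC":
        pattern = [(p["t_iso"], False), (p["t_sc"], True)]
    elif cat == "PSC":
        pattern = [(p["t_iso"] / 2, False), (p["t_sc"] / 2, True)] * 2
    else:  # pragma: no cover
        raise ModelError(cat)

    grow = "ex" in model.flags
    base1 = p["nu_a1"] if grow else p["nu1"]
    base2 = p["nu_a2"] if grow else p["nu2"]
    epochs = [
        Epoch(dur, base1, base1, base2, base2, m12 if mig else 0.0, m21 if mig else 0.0)
        for dur, mig in pattern
        if dur > 0
    ]
    if grow:
        mig_now = cat in ("IM", "SC", "PSC")
        epochs.append(
            Epoch(p["t_scg"], base1, p["nu1"], base2, p["nu2"],
                  m12 if mig_now else 0.0, m21 if mig_now else 0.0)
        )
    return EpochSchedule(epochs, nu_anc=p.get("nu_anc", 1.0))


# ---------------------------------------------------------------------------
# Locus-class mixtures (2N / 2M2P)
# ---------------------------------------------------------------------------

BASE_CLASS = "base"
NOMIG_POP1 = "no-mig-into-pop1"
NOMIG_POP2 = "no-mig-into-pop2"
REDUCED_NE = "reduced-Ne"


def locus_class_mixture(model: DemographicModel) -> list:
    """Expand the 2N/2M2P flags into (weight, class label, base-flag model).

    The 2M2P classes zero the migration rate into the focal population; the
    2N class multiplies *all* sizes (current, post-split and ancestral) by
    the background-selection factor ``bf``, modelling a locus-scale
    reduction of effective size along the entire history.
    """
    base_flags = model.flags & {"ex"}
    p = dict(model.params)
    for key in ("P1", "P2", "nr", "bf"):
        p.pop(key, None)
    base = DemographicModel(model.category, base_flags, p)
    if "2M2P" in model.flags:
        P1, P2 = model.params["P1"], model.params["P2"]
        no1 = replace(base, params={**p, "M12": 0.0})
        no2 = replace(base, params={**p, "M21": 0.0})
        return [(1 - P1 - P2, BASE_CLASS, base), (P1, NOMIG_POP1, no1), (P2, NOMIG_POP2, no2)]
    if "2N" in model.flags:
        nr, bf = model.params["nr"], model.params["bf"]
        scaled = dict(p)
        for key in list(scaled):
            if key.startswith("nu"):
                scaled[key] = scaled[key] * bf
        scaled["nu_anc"] = p.get("nu_anc", 1.0) * bf
        red = replace(base, params=scaled)
        return [(1 - nr, BASE_CLASS, base), (nr, REDUCED_NE, red)]
    return [(1.0, BASE_CLASS, base)]


# ---------------------------------------------------------------------------
# Exact engine: lineage-configuration Markov chain
# ---------------------------------------------------------------------------
#
# The state is the multiset of ancestral lineages, each labelled by the
# number of descendants it subtends in each present-day sample and by its
# current population.  Coalescence (rate 1/nu per pair within a population)
# and migration (rate M_ij per lineage, backward in time) define a finite
# continuous-time Markov chain; the expected SFS entry (i, j) is, up to the
# mutation-rate constant, the expected total time carried by lineages of
# type (i, j).  Occupancies are accumulated through each epoch with a Van
# Loan block-matrix exponential and the final (ancestral, constant-size)
# epoch is resolved by a direct absorbing-chain linear solve.

@functools.lru_cache(maxsize=8)
def _config_space(n1: int, n2: int):
    init = tuple(sorted([(1, 0, 0)] * n1 + [(0, 1, 1)] * n2))
    states = [init]
    index = {init: 0}
    trans = {k: [] for k in ("c0", "c1", "m01", "m10")}
    i = 0
    while i < len(states):
        cnt = Counter(states[i])
        types = list(cnt)
        for x in range(len(types)):
            for y in range(x, len(types)):
                t1, t2 = types[x], types[y]
                if t1[2] != t2[2]:
                    continue
                npairs = cnt[t1] * (cnt[t1] - 1) // 2 if x == y else cnt[t1] * cnt[t2]
                if npairs == 0:
                    continue
                new = Counter(cnt)
                new[t1] -= 1
                new[t2] -= 1
                new[(t1[0] + t2[0], t1[1] + t2[1], t1[2])] += 1
                ns = tuple(sorted(new.elements()))
                if ns not in index:
                    index[ns] = len(states)
                    states.append(ns)
                trans["c0" if t1[2] == 0 else "c1"].append((i, index[ns], float(npairs)))
        for t in types:
            a, b, loc = t
            new = Counter(cnt)
            new[t] -= 1
            new[(a, b, 1 - loc)] += 1
            ns = tuple(sorted(new.elements()))
            if ns not in index:
                index[ns] = len(states)
                states.append(ns)
            trans["m01" if loc == 0 else "m10"].append((i, index[ns], float(cnt[t])))
        i += 1

    S = len(states)
    mats = {}
    for k, lst in trans.items():
        if lst:
            frm, to, c = zip(*lst)
            M = sp.coo_matrix((c, (to, frm)), shape=(S, S)).tocsr()  # rate[to, from]
        else:
            M = sp.csr_matrix((S, S))
        mats[k] = (M - sp.diags(np.asarray(M.sum(axis=0)).ravel())).tocsr()

    ntypes = (n1 + 1) * (n2 + 1)
    rows, cols, vals = [], [], []
    for si, st in enumerate(states):
        for a, b, _loc in st:
            if (a, b) != (n1, n2):  # the root lineage carries no observable mutations
                rows.append(si)
                cols.append(a * (n2 + 1) + b)
                vals.append(1.0)
    K = sp.coo_matrix((vals, (rows, cols)), shape=(S, ntypes)).tocsr()

    # merge map: forget locations (all lineages to population 0) at the split
    merge_to = np.array(
        [index[tuple(sorted((a, b, 0) for a, b, _ in st))] for st in states], dtype=int
    )
    # transient (pre-MRCA) states of the merged, single-population chain
    anc_transient = np.array(
        [si for si, st in enumerate(states) if len(st) > 1 and all(l == 0 for *_, l in st)],
        dtype=int,
    )
    lineage_count = np.array([len(st) for st in states])
    return states, index, mats, K, merge_to, anc_transient, lineage_count


def _epoch_steps(epoch: Epoch, growth_steps: int):
    """Discretize an epoch into piecewise-constant backward-time steps."""
    if not epoch.is_exponential:
        return [(epoch.duration, epoch.nu1_start, epoch.nu2_start)]
    steps = []
    k = max(growth_steps, 1)
    for i in range(k):
        s0, s1 = i / k, (i + 1) / k
        smid = (s0 + s1) / 2
        nu1 = epoch.nu1_start * (epoch.nu1_end / epoch.nu1_start) ** smid
        nu2 = epoch.nu2_start * (epoch.nu2_end / epoch.nu2_start) ** smid
        steps.append((epoch.duration / k, nu1, nu2))
    return steps


def _uniformized_step(Q, p, t):
    """Propagate p over time t and return (p(t), integral of p over [0, t]).

    Uniformization: with Lambda the fastest outflow rate and
    P = I + Q/Lambda, e^{Qt} p = sum_k Pois(k; Lambda t) P^k p and the
    occupancy integral has Poisson survival-function weights
    (1/Lambda) P(N > k).  All terms are non-negative, so the recursion is
    unconditionally stable.
    """
    lam = float(np.abs(Q.diagonal()).max())
    if lam * t < 1e-14:
        return p, p * t
    P = sp.eye(Q.shape[0], format="csr") + Q / lam
    m = lam * t
    k_max = int(m + 8.0 * np.sqrt(m + 1) + 25)
    v = p
    pois = np.exp(-m)  # Pois(0; m)
    tail = 1.0 - pois   # P(N > 0)
    pout = pois * v
    integral = tail * v
    for k in range(1, k_max + 1):
        v = P @ v
        pois *= m / k
        tail -= pois
        pout += pois * v
        if tail <= 0:
            break
        integral += tail * v
    return pout, integral / lam


def _expected_sfs_exact(schedule: EpochSchedule, n1: int, n2: int, growth_steps: int = 20):
    states, index, mats, K, merge_to, anc_transient, lin_count = _config_space(n1, n2)
    S = len(states)
    ntypes = (n1 + 1) * (n2 + 1)
    p = np.zeros(S)
    p[index[tuple(sorted([(1, 0, 0)] * n1 + [(0, 1, 1)] * n2))]] = 1.0
    A = np.zeros(ntypes)

    done = False
    for epoch in reversed(schedule.epochs):
        if epoch.duration <= 0 or done:
            continue
        for dur, nu1, nu2, in reversed(_epoch_steps(epoch, growth_steps)):
            Q = mats["c0"] / nu1 + mats["c1"] / nu2
            if epoch.m12:
                Q = Q + mats["m01"] * epoch.m12
            if epoch.m21:
                Q = Q + mats["m10"] * epoch.m21
            # Lineage counts only decrease, so the chain restricted to states
            # at or below the currently occupied maximum is closed; shrinking
            # the active set as coalescences fire keeps the uniformization
            # rate (and matvec count) tied to the remaining dynamics.
            t_left = dur
            L_active, Qs, Ks, act = None, None, None, None
            while t_left > 1e-15:
                L = int(lin_count[p > 1e-12].max())
                if L == 1:
                    done = True  # fully coalesced: the SFS stops accruing
                    break
                if L != L_active:
                    act = lin_count <= L
                    Qs = Q[np.ix_(act, act)].tocsr()
                    Ks = K[act]
                    L_active = L
                rate = float(np.abs(Qs.diagonal()).max())
                step = t_left if rate * t_left <= 200 else 200.0 / rate
                ps, occ = _uniformized_step(Qs, p[act], step)
                p = np.zeros(S)
                p[act] = ps
                A = A + Ks.T @ occ
                t_left -= step
            if done:
                break

    pm = np.zeros(S)
    np.add.at(pm, merge_to, p)
    Q = mats["c0"] / schedule.nu_anc
    Qtt = Q[np.ix_(anc_transient, anc_transient)].tocsc()
    occupancy = spsolve(-Qtt, pm[anc_transient])
    A = A + K[anc_transient].T @ occupancy
    return A.reshape(n1 + 1, n2 + 1)


# ---------------------------------------------------------------------------
# Monte-Carlo engine (msprime)
# ---------------------------------------------------------------------------

def to_msprime_demography(schedule: EpochSchedule, Nref: float = 1.0, ploidy: int = 1):
    """Convert an epoch schedule into an msprime Demography.

    With ``ploidy=1`` and ``Nref=1`` the simulator's time unit equals the
    scaled coalescent unit (2*Nref generations) used throughout this module;
    with ``ploidy=2`` sizes are ``nu*Nref`` diploids and times are
    ``t*2*Nref`` generations.
    """
    import msprime

    time_scale = ploidy * Nref  # generations per scaled time unit
    back = list(reversed(schedule.epochs))
    first = back[0] if back else None
    dem = msprime.Demography()
    dem.add_population(name="pop1", initial_size=(first.nu1_end if first else 1.0) * Nref)
    dem.add_population(name="pop2", initial_size=(first.nu2_end if first else 1.0) * Nref)
    dem.add_population(name="anc", initial_size=schedule.nu_anc * Nref)

    t = 0.0
    for epoch in back:
        # backward-time exponential rate so that size at the epoch's old edge
        # equals the forward start size
        if epoch.is_exponential:
            g1 = np.log(epoch.nu1_end / epoch.nu1_start) / (epoch.duration * time_scale)
            g2 = np.log(epoch.nu2_end / epoch.nu2_start) / (epoch.duration * time_scale)
        else:
            g1 = g2 = 0.0
        dem.add_population_parameters_change(
            time=t, population="pop1", initial_size=epoch.nu1_end * Nref, growth_rate=g1)
        dem.add_population_parameters_change(
            time=t, population="pop2", initial_size=epoch.nu2_end * Nref, growth_rate=g2)
        # backward-time lineage movement pop1 -> pop2 at rate M12 (= forward
        # migration into pop1), per scaled time unit
        dem.add_migration_rate_change(
            time=t, rate=epoch.m12 / time_scale, source="pop1", dest="pop2")
        dem.add_migration_rate_change(
            time=t, rate=epoch.m21 / time_scale, source="pop2", dest="pop1")
        t += epoch.duration * time_scale
    dem.add_population_split(time=t, derived=["pop1", "pop2"], ancestral="anc")
    dem.sort_events()
    return dem


def _expected_sfs_mc(schedule, n1, n2, n_replicates=5000, seed=None, return_se=False):
    import msprime

    dem = to_msprime_demography(schedule)
    acc = np.zeros((n1 + 1, n2 + 1))
    acc2 = np.zeros_like(acc)
    reps = msprime.sim_ancestry(
        samples={"pop1": n1, "pop2": n2}, ploidy=1, demography=dem,
        num_replicates=n_replicates, random_seed=None if seed is None else max(1, int(seed)),
    )
    for ts in reps:
        a = ts.allele_frequency_spectrum(
            sample_sets=[ts.samples(0), ts.samples(1)],
            mode="branch", polarised=True, span_normalise=False,
        )
        acc += a
        acc2 += a * a
    mean = acc / n_replicates
    if not return_se:
        return mean
    se = np.sqrt(np.maximum(acc2 / n_replicates - mean**2, 0.0) / n_replicates)
    return mean, se


# ---------------------------------------------------------------------------
# Expected SFS with mixtures and mis-polarization
# ---------------------------------------------------------------------------

def apply_misid(expected: np.ndarray, O: float) -> np.ndarray:
    """Ancestral-misidentification transform: O*M + (1-O)*reverse(M).

    ``reverse`` flips both axes (derived counts i -> n1-i, j -> n2-j);
    ``O`` is the probability a site is correctly polarized.
    """
    if not 0.5 < O <= 1.0:
        raise ModelError("O must lie in (0.5, 1]")
    M = np.asarray(expected, dtype=float)
    return O * M + (1.0 - O) * M[::-1, ::-1]


def expected_sfs(
    model: DemographicModel,
    n1: int,
    n2: int,
    engine: str = "exact",
    n_replicates: int = 5000,
    seed=None,
    growth_steps: int = 20,
) -> np.ndarray:
    """Expected unfolded joint SFS under a scenario, up to a multiplicative
    mutation-rate constant.

    Locus-class flags expand into weighted mixtures of base spectra;
    mis-polarization (parameter ``O``, if present) is applied last.
    """
    if engine == "exact" and n1 + n2 > EXACT_ENGINE_MAX:
        raise ModelError(
            f"exact engine supports n1+n2 <= {EXACT_ENGINE_MAX}; use engine='monte-carlo'")
    if engine not in ("exact", "monte-carlo"):
        raise ModelError(f"unsupported engine {engine!r}")

    total = np.zeros((n1 + 1, n2 + 1))
    for weight, _label, sub in locus_class_mixture(model):
        if weight == 0:
            continue
        schedule = build_epochs(sub)
        if engine == "exact":
            part = _expected_sfs_exact(schedule, n1, n2, growth_steps)
        else:
            part = _expected_sfs_mc(schedule, n1, n2, n_replicates=n_replicates, seed=seed)
        total += weight * part
    O = model.params.get("O")
    if O is not None and O < 1.0:
        total = apply_misid(total, O)
    return total


# ---------------------------------------------------------------------------
# Composite likelihood, fitting, AIC
# ---------------------------------------------------------------------------

def composite_loglik(observed: JointSFS, expectation: np.ndarray) -> float:
    """Poisson composite log-likelihood with the scale profiled analytically.

    With observed counts D and model expectation M over unmasked entries,
    the profiled scale is ``alpha = sum(D)/sum(M)`` and

        lnL = sum[ D*ln(alpha*M) - alpha*M - ln Gamma(D+1) ].

    Entries where the expectation is zero but data are observed yield
    ``-inf`` (with a warning).  An all-zero observation returns 0 by the
    empty-data convention (alpha-hat = 0).
    """
    M = np.asarray(expectation, dtype=float)
    if M.shape != observed.counts.shape:
        raise ModelError("expectation shape does not match observed SFS")
    free = ~observed.mask
    D = observed.counts[free]
    m = np.clip(M[free], 0.0, None)
    sD = D.sum()
    if sD == 0:
        return 0.0
    sM = m.sum()
    if sM <= 0:
        warnings.warn("model expectation is identically zero")
        return -np.inf
    lam = (sD / sM) * m
    if ((lam == 0) & (D > 0)).any():
        warnings.warn("zero expectation where data observed; composite lnL = -inf")
        return -np.inf
    ok = lam > 0
    return float(np.sum(D[ok] * np.log(lam[ok]) - lam[ok] - gammaln(D[ok] + 1)))


#: default optimization bounds by parameter kind
DEFAULT_BOUNDS = {
    "nu": (1e-3, 1e2),
    "M": (1e-3, 40.0),
    "t": (1e-3, 20.0),
    "O": (0.51, 1.0),
    "P": (1e-3, 0.999),
    "nr": (1e-3, 0.999),
    "bf": (1e-2, 1.0),
}

_LOG_SCALE_PREFIXES = ("nu", "M", "t_")


def _param_kind(name: str) -> str:
    if name.startswith("nu"):
        return "nu"
    if name.startswith("M"):
        return "M"
    if name.startswith("t_"):
        return "t"
    if name in ("P1", "P2"):
        return "P"
    return name


def _bounds_for(names, bounds=None):
    out = {}
    user = bounds or {}
    for n in names:
        out[n] = user.get(n, DEFAULT_BOUNDS[_param_kind(n)])
    return out


def min_scaled_time(years: float, Nref: float, generation_time_years: float = 1.0) -> float:
    """Scaled-time lower bound corresponding to a duration in years
    (e.g. the ~50,000-year minimum for contact/isolation episodes)."""
    return years / (2.0 * Nref * generation_time_years)


class _Transform:
    """Box-constrained <-> unconstrained coordinates: scale parameters move
    on log10 within their bounds, fractions on a linear scale, both through
    a logistic map."""

    def __init__(self, names, bounds):
        self.names = list(names)
        self.lo = np.empty(len(self.names))
        self.hi = np.empty(len(self.names))
        self.log = np.zeros(len(self.names), dtype=bool)
        for i, n in enumerate(self.names):
            lo, hi = bounds[n]
            self.log[i] = any(n.startswith(p) for p in _LOG_SCALE_PREFIXES)
            self.lo[i], self.hi[i] = (np.log10(lo), np.log10(hi)) if self.log[i] else (lo, hi)

    def to_z(self, x):
        x = np.asarray(x, dtype=float)
        u = np.where(self.log, np.log10(np.maximum(x, 1e-300)), x)
        frac = np.clip((u - self.lo) / (self.hi - self.lo), 1e-9, 1 - 1e-9)
        return logit(frac)

    def to_x(self, z):
        u = self.lo + (self.hi - self.lo) * expit(np.asarray(z, dtype=float))
        return np.where(self.log, 10.0**u, u)

    def draw(self, rng):
        """Log-uniform (scale params) / uniform (fractions) draw within bounds."""
        u = rng.uniform(self.lo, self.hi)
        return np.where(self.log, 10.0**u, u)


@dataclass
class FitResult:
    """Best fit of one scenario to an observed joint SFS."""

    model: DemographicModel
    params: dict
    loglik: float
    k: int
    aic: float
    starts: list = field(default_factory=list)
    fixed: dict = field(default_factory=dict)
    n_obs: float = 0.0
    bootstrap_sd: dict | None = None
    bootstrap_bands: dict | None = None
    flagged: bool = False


def fit_model(
    observed: JointSFS,
    model,
    n_starts: int = 30,
    seed=None,
    bounds=None,
    fixed=None,
    engine: str = "exact",
    init_params=None,
    optimizer_options=None,
    growth_steps: int = 20,
) -> FitResult:
    """Fit one scenario by multi-start derivative-free local optimization.

    Starts are drawn log-uniformly (uniformly for fraction parameters)
    within the bounds; each start runs Nelder-Mead in transformed
    coordinates and the replicate with the highest composite likelihood is
    retained.  ``fixed`` pins parameters (e.g. ``{"O": 1.0}`` for perfectly
    polarized data); fixed parameters do not count toward ``k``.
    ``init_params`` adds one start at the given parameter values (used by
    the bootstrap refits).
    """
    if isinstance(model, str):
        model = DemographicModel.from_name(model)
    fixed = dict(fixed or {})
    free_names = [n for n in model.param_names() if n not in fixed]
    tf = _Transform(free_names, _bounds_for(free_names, bounds))
    rng = np.random.default_rng(seed)
    opts = {"maxfev": 2000, "xatol": 1e-4, "fatol": 1e-7, **(optimizer_options or {})}

    n1, n2 = observed.n1, observed.n2
    if not observed.polarized:
        raise ModelError("fitting requires an unfolded (polarized) SFS")

    def objective(z):
        x = tf.to_x(z)
        params = dict(zip(free_names, x))
        params.update(fixed)
        if "P1" in params and "P2" in params and params["P1"] + params["P2"] >= 1:
            return 1e8 * (params["P1"] + params["P2"])
        m = DemographicModel(model.category, model.flags, params)
        try:
            exp_sfs = expected_sfs(m, n1, n2, engine=engine, growth_steps=growth_steps)
        except (ModelError, FloatingPointError):
            return 1e12
        ll = composite_loglik(observed, exp_sfs)
        return 1e12 if not np.isfinite(ll) else -ll

    start_points = []
    if init_params is not None:
        start_points.append(np.array([init_params[n] for n in free_names], dtype=float))
    while len(start_points) < n_starts + (init_params is not None):
        x0 = tf.draw(rng)
        if "P1" in free_names and "P2" in free_names:
            i1, i2 = free_names.index("P1"), free_names.index("P2")
            if x0[i1] + x0[i2] >= 1:
                continue
        start_points.append(x0)

    # Stage 1: a bounded local search from every start; stage 2: polish the
    # best stage-1 replicate with the full budget.
    coarse = {**opts, "maxfev": max(150, opts["maxfev"] // 10), "fatol": 1e-3, "xatol": 1e-2}
    starts, best = [], None
    for x0 in start_points:
        res = minimize(objective, tf.to_z(x0), method="Nelder-Mead",
                       options={**coarse, "maxiter": coarse["maxfev"]})
        rec = {"params": dict(zip(free_names, tf.to_x(res.x))), "loglik": -res.fun,
               "nfev": res.nfev, "converged": bool(res.success), "z": res.x}
        starts.append(rec)
        if best is None or rec["loglik"] > best["loglik"]:
            best = rec
    if best is None or not np.isfinite(best["loglik"]):
        raise FitError(f"no start converged for {model.name}; starts: {starts}")
    # polish the leading candidates with restarted Nelder-Mead (a fresh
    # simplex escapes the premature shrinkage NM is prone to in 6+ dims)
    top = sorted(starts, key=lambda r: -r["loglik"])[: min(3, len(starts))]
    for cand in top:
        z, ll_prev = cand["z"], -np.inf
        for _round in range(6):
            res = minimize(objective, z, method="Nelder-Mead",
                           options={**opts, "maxiter": opts["maxfev"]})
            z = res.x
            polished = {"params": dict(zip(free_names, tf.to_x(z))), "loglik": -res.fun,
                        "nfev": res.nfev, "converged": bool(res.success)}
            starts.append(polished)
            if polished["loglik"] >= best["loglik"]:
                best = polished
            if polished["loglik"] - ll_prev < 0.01:
                break
            ll_prev = polished["loglik"]
    for rec in starts:
        rec.pop("z", None)

    params = {**best["params"], **fixed}
    k = len(free_names)
    ll = best["loglik"]
    fitted = DemographicModel(model.category, model.flags, params)
    return FitResult(
        model=fitted, params=params, loglik=ll, k=k, aic=2 * k - 2 * ll,
        starts=starts, fixed=fixed, n_obs=observed.total(),
    )


def aic(fit: FitResult) -> float:
    """AIC = 2k - 2 lnL with k the number of free parameters."""
    return 2 * fit.k - 2 * fit.loglik


def rank_models(fits) -> pd.DataFrame:
    """Rank fitted scenarios by ascending AIC (with delta-AIC)."""
    rows = [
        {"model": f.model.name, "k": f.k, "loglik": f.loglik, "aic": aic(f)} for f in fits
    ]
    df = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


def star_band(sd: float, estimate: float) -> str:
    """Uncertainty band coding: '' below +/-20% of the point estimate,
    '*' for 20-50%, '**' for 50-150%, '***' beyond."""
    if estimate == 0:
        return "***" if sd > 0 else ""
    r = abs(sd / estimate)
    if r < 0.2:
        return ""
    if r < 0.5:
        return "*"
    if r <= 1.5:
        return "**"
    return "***"


def bootstrap_uncertainty(
    model,
    bootstrap_sfs_list,
    best_fit: FitResult,
    seed=None,
    engine: str = "exact",
    optimizer_options=None,
) -> FitResult:
    """Refit bootstrap spectra from the best fit; SDs and star bands per parameter.

    Each bootstrap replicate is refitted starting from the best-fit
    parameters (a local polish).  If more than 20% of replicate fits fail,
    the result is flagged.
    """
    if isinstance(model, str):
        model = DemographicModel.from_name(model)
    free_names = [n for n in model.param_names() if n not in best_fit.fixed]
    estimates, failures = [], 0
    opts = {"maxfev": 400, "xatol": 1e-3, "fatol": 1e-6, **(optimizer_options or {})}
    for i, rep in enumerate(bootstrap_sfs_list):
        try:
            f = fit_model(
                rep, model, n_starts=0, seed=None if seed is None else seed + i,
                fixed=best_fit.fixed, engine=engine,
                init_params={n: best_fit.params[n] for n in free_names},
                optimizer_options=opts,
            )
            estimates.append([f.params[n] for n in free_names])
        except FitError:
            failures += 1
    flagged = failures > 0.2 * len(bootstrap_sfs_list)
    if flagged:
        warnings.warn(f"{failures}/{len(bootstrap_sfs_list)} bootstrap refits failed")
    est = np.array(estimates)
    sds = est.std(axis=0, ddof=1) if len(est) > 1 else np.zeros(len(free_names))
    sd = dict(zip(free_names, sds))
    bands = {n: star_band(sd[n], best_fit.params[n]) for n in free_names}
    return replace(best_fit, bootstrap_sd=sd, bootstrap_bands=bands, flagged=flagged)


def to_demographic_units(
    fit, Nref: float, mu: float | None = None, generation_time_years: float = 1.0
) -> dict:
    """Convert scaled parameters to demographic units.

    Sizes become ``nu * Nref`` diploid individuals, times ``t * 2 * Nref``
    generations (reported in years via the generation time), and migration
    ``m = M / (2 * Nref)`` per generation.  ``Nref`` itself is reported as
    the ancestral size ``Na12``.
    """
    params = fit.params if isinstance(fit, FitResult) else dict(fit)
    if Nref <= 0:
        raise ModelError("Nref must be positive")
    out = {"Na12": Nref}
    rename = {"nu1": "N1", "nu2": "N2", "nu_a1": "Na1", "nu_a2": "Na2"}
    for name, value in params.items():
        if name.startswith("nu"):
            out[rename.get(name, name)] = value * Nref
        elif name.startswith("M"):
            out["m" + name[1:]] = value / (2.0 * Nref)
        elif name.startswith("t_"):
            gens = value * 2.0 * Nref
            out["T" + name[2:] + "_generations"] = gens
            out["T" + name[2:] + "_years"] = gens * generation_time_years
        else:
            out[name] = value
    return out


def fits_to_table(fits, Nref: float | None = None, generation_time_years: float = 1.0):
    """Comparison table across fitted scenarios (optionally in demographic units)."""
    rows = []
    for f in fits:
        row = {"model": f.model.name, "k": f.k, "logLikelihood": f.loglik, "AIC": aic(f)}
        row.update(
            to_demographic_units(f, Nref, generation_time_years=generation_time_years)
            if Nref
            else f.params
        )
        if f.bootstrap_bands:
            for n, b in f.bootstrap_bands.items():
                row[f"band_{n}"] = b
        rows.append(row)
    return pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
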