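"""Individual-based forward simulator of bottlenecked diploid populations.

The model: discrete generations, separate sexes, random mating (each
offspring draws a uniformly random father, so polygyny is allowed), Poisson
fecundity per female, hard viability selection at the offspring level, and
random culling of survivors to the patch carrying capacity K.  Loci are
unlinked (independent Mendelian sampling per locus, equivalent to free
recombination) and biallelic; the derived allele at each of the
``n_deleterious_loci`` selected loci carries a selection coefficient s drawn
from a gamma distribution, with dominance tied to s through the exponential
map h = exp(−rate·s)/2 — strongly deleterious mutations are nearly
recessive, weak ones nearly additive.  Mutation is recurrent
(ancestral→derived at µ, back-mutation at a much lower rate).

Fitness is multiplicative across loci, w = Π (1−h_i s_i)^{het} (1−s_i)^{hom}
(an additive alternative is available).  Genetic load of a patch is
L = 1 − W_mean/W_max over its females, where W is the expected number of
surviving offspring (fecundity × w; the fecundity factor cancels in L).

A patch goes extinct when a generation leaves no survivors or loses one
sex; extinct patches stay empty unless re-founded.  Founding of new
populations is modelled as migration of offspring: founders are drawn
without replacement from an offspring pool of the source patch, with the
sex ratio forced to 1:1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable, make_manifest
from .scenario import Founding, Scenario, SetK, harmonic_mean  # noqa: F401

logger = logging.getLogger(__name__)

FEMALE, MALE = 1, 0


@dataclass
class SelectionParams:
    """Genetic architecture and life-history parameters.

    ``gamma_mean_s``/``gamma_shape`` parametrize the distribution of
    selection coefficients (scale = mean/shape); ``dominance_rate`` is the
    decay constant of the dominance map h = exp(−rate·s)/2;
    ``initial_derived_freq`` seeds every locus at the start of the burn-in
    (the expected frequency at mutation–selection balance for the mean
    effect size); ``fecundity_mean`` is the mean number of offspring per
    female.  Set ``s_values`` to an explicit array to bypass the gamma draw.
    """

    n_deleterious_loci: int = 5000
    n_neutral_loci: int = 500
    gamma_mean_s: float = 0.01
    gamma_shape: float = 0.3
    dominance_rate: float = 51.0
    mu: float = 5e-05
    back_mu: float = 5e-07
    initial_derived_freq: float = 0.0014
    fecundity_mean: float = 5.0
    fitness_model: str = "multiplicative"
    s_values: np.ndarray | None = None

    def __post_init__(self):
        for name in ("mu", "back_mu", "initial_derived_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1]")
        if self.gamma_mean_s <= 0 or self.gamma_shape <= 0:
            raise ValueError("gamma parameters must be positive")
        if self.n_deleterious_loci < 0 or self.n_neutral_loci < 0:
            raise ValueError("locus counts must be >= 0")
        if self.fitness_model not in ("multiplicative", "additive"):
            raise ValueError(f"unknown fitness model {self.fitness_model!r}")

    @property
    def n_loci(self) -> int:
        return self.n_deleterious_loci + self.n_neutral_loci


def sample_selection_coefficients(
    n: int, gamma_mean: float = 0.01, gamma_shape: float = 0.3, seed=None
) -> np.ndarray:
    """Draw i.i.d. selection coefficients from Gamma(shape, mean/shape)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.gamma(gamma_shape, gamma_mean / gamma_shape, size=n)


def dominance_of(s, dominance_rate: float = 51.0):
    """Dominance coefficient h = exp(−rate·s)/2 ∈ (0, 0.5]."""
    return np.exp(-dominance_rate * np.asarray(s, dtype=float)) / 2.0


@dataclass
class Patch:
    """One deme: genotype dosages (individuals × loci) and sexes."""

    dosage: np.ndarray  # int8, derived-allele dosage 0/1/2
    sex: np.ndarray  # int8, FEMALE/MALE
    k: int
    extinct: bool = False

    @property
    def size(self) -> int:
        return 0 if self.extinct else self.dosage.shape[0]


@dataclass
class SimState:
    """Full simulator state: patches plus the shared genetic architecture."""

    patches: dict
    s: np.ndarray
    h: np.ndarray
    params: SelectionParams
    generation: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def extant_patches(self) -> list:
        return [name for name, p in self.patches.items() if not p.extinct and p.size > 0]


def genotype_fitness(
    dosage: np.ndarray, s: np.ndarray, h: np.ndarray, model: str = "multiplicative"
) -> np.ndarray:
    """Viability of each individual from its derived-allele dosages.

    Multiplicative: w = Π (1 − h_i s_i)^{het_i} (1 − s_i)^{hom_i}; a
    homozygous lethal (s = 1) yields w = 0.  Additive: w = max(0, 1 − Σ
    penalties).  Neutral loci (s = 0) contribute nothing either way.
    """
    dosage = np.atleast_2d(dosage)
    het = (dosage == 1).astype(np.float64)
    hom = (dosage == 2).astype(np.float64)
    if model == "multiplicative":
        with np.errstate(divide="ignore"):
            log_het = np.log1p(-h * s)
            log_hom = np.log1p(-s)
        logw = het @ log_het + hom @ log_hom
        return np.exp(logw)
    if model == "additive":
        return np.clip(1.0 - (het @ (h * s) + hom @ s), 0.0, None)
    raise ValueError(f"unknown fitness model {model!r}")


def initialize_burn_in(
    params: SelectionParams, k: int, seed=None, patch_name: str = "gp"
) -> SimState:
    """One patch of K individuals seeded at the initial derived frequency.

    Selection coefficients are drawn (or taken from ``params.s_values``),
    dominance follows the exponential map, neutral loci get s = 0.  Each
    allele copy at every locus carries the derived state with probability
    ``initial_derived_freq``; sexes are Bernoulli(1/2).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if params.s_values is not None:
        s_del = np.asarray(params.s_values, dtype=float)
        if len(s_del) != params.n_deleterious_loci:
            raise ValueError("s_values length must equal n_deleterious_loci")
    elif params.n_deleterious_loci > 0:
        s_del = sample_selection_coefficients(
            params.n_deleterious_loci, params.gamma_mean_s, params.gamma_shape, rng
        )
    else:
        s_del = np.empty(0)
    s = np.concatenate([s_del, np.zeros(params.n_neutral_loci)])
    h = np.where(s > 0, dominance_of(s, params.dominance_rate), 0.5)
    f0 = params.initial_derived_freq
    dosage = rng.binomial(2, f0, size=(k, params.n_loci)).astype(np.int8)
    sex = rng.integers(0, 2, size=k).astype(np.int8)
    patch = Patch(dosage=dosage, sex=sex, k=k)
    return SimState(patches={patch_name: patch}, s=s, h=h, params=params, rng=rng)


def _offspring_pool(
    patch: Patch, state: SimState, n_exact: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Produce offspring (dosage, sex) by random mating with mutation.

    With ``n_exact`` the pool has exactly that many offspring (used for
    founding); otherwise each female contributes Poisson(fecundity) young.
    Gamete allele at a locus is Bernoulli(g/2) in the parent's dosage g,
    then mutates 0→1 at µ and 1→0 at the back rate — equivalently the
    transmitted-derived probability is (g/2)(1−back_µ) + (1−g/2)µ.
    """
    p = state.params
    rng = state.rng
    females = np.flatnonzero(patch.sex == FEMALE)
    males = np.flatnonzero(patch.sex == MALE)
    if len(females) == 0 or len(males) == 0:
        return np.empty((0, p.n_loci), np.int8), np.empty(0, np.int8)
    if n_exact is None:
        brood = rng.poisson(p.fecundity_mean, size=len(females))
        mothers = np.repeat(females, brood)
    else:
        mothers = rng.choice(females, size=n_exact, replace=True)
    n_off = len(mothers)
    if n_off == 0:
        return np.empty((0, p.n_loci), np.int8), np.empty(0, np.int8)
    fathers = rng.choice(males, size=n_off, replace=True)
    half_m = patch.dosage[mothers].astype(np.float64) / 2.0
    half_f = patch.dosage[fathers].astype(np.float64) / 2.0
    pm = half_m * (1.0 - p.back_mu) + (1.0 - half_m) * p.mu
    pf = half_f * (1.0 - p.back_mu) + (1.0 - half_f) * p.mu
    dosage = (
        (rng.random(pm.shape) < pm).astype(np.int8)
        + (rng.random(pf.shape) < pf).astype(np.int8)
    )
    sex = rng.integers(0, 2, size=n_off).astype(np.int8)
    return dosage, sex


def advance_generation(state: SimState) -> SimState:
    """One full generation in every extant patch (in place).

    Reproduction, hard viability selection (offspring survive with
    probability w), then random culling to K.  A patch with no survivors or
    a single surviving sex is marked extinct.
    """
    for name in state.extant_patches():
        patch = state.patches[name]
        dosage, sex = _offspring_pool(patch, state)
        if len(sex) == 0:
            patch.extinct = True
            logger.info("patch %s extinct at generation %d", name, state.generation)
            continue
        w = genotype_fitness(dosage, state.s, state.h, state.params.fitness_model)
        alive = state.rng.random(len(w)) < w
        dosage, sex = dosage[alive], sex[alive]
        if len(sex) > patch.k:
            keep = state.rng.choice(len(sex), size=patch.k, replace=False)
            dosage, sex = dosage[keep], sex[keep]
        if len(sex) == 0 or len(np.unique(sex)) < 2:
            patch.extinct = True
            patch.dosage = dosage[:0]
            patch.sex = sex[:0]
            logger.info("patch %s extinct at generation %d", name, state.generation)
            continue
        patch.dosage, patch.sex = dosage, sex
    state.generation += 1
    return state


def found_population(state: SimState, event: Founding) -> SimState:
    """Found ``event.patch`` from offspring of its source patch(es).

    Founders are sampled without replacement from a fresh offspring pool of
    each source; sexes are forced to a 1:1 ratio (odd counts: extra female).
    """
    founder_dos, founder_sex = [], []
    for src, n in event.sources.items():
        patch = state.patches.get(src)
        if patch is None or patch.extinct or patch.size == 0:
            raise ValueError(f"founding source {src!r} is not extant")
        if patch.size < n:
            raise ValueError(
                f"source {src!r} has {patch.size} individuals, "
                f"fewer than the {n} founders requested"
            )
        pool_dos, _pool_sex = _offspring_pool(patch, state, n_exact=max(2 * n, 20))
        if len(pool_dos) < n:
            raise ValueError(f"source {src!r} produced too few offspring")
        pick = state.rng.choice(len(pool_dos), size=n, replace=False)
        dos = pool_dos[pick]
        n_f = n // 2 + n % 2  # extra female when odd
        sex = np.array([FEMALE] * n_f + [MALE] * (n - n_f), dtype=np.int8)
        founder_dos.append(dos)
        founder_sex.append(sex)
    dosage = np.vstack(founder_dos)
    sex = np.concatenate(founder_sex)
    k = event.k if event.k is not None else state.patches.get(
        event.patch, Patch(dosage[:0], sex[:0], len(sex))
    ).k
    state.patches[event.patch] = Patch(dosage=dosage, sex=sex, k=int(k or len(sex)))
    return state


# -- load reporting --------------------------------------------------------

DEFAULT_CATEGORY_EDGES = {"neutral": (0.0, 0.0), "mild": (0.0, 0.1), "high": (0.1, np.inf)}


def locus_categories(s: np.ndarray, edges: dict | None = None) -> np.ndarray:
    """Label loci by effect size: neutral (s = 0), mild, high (s ≥ 0.1)."""
    edges = edges or DEFAULT_CATEGORY_EDGES
    out = np.empty(len(s), dtype=object)
    out[:] = "mild"
    out[s == 0] = "neutral"
    out[s >= edges["high"][0]] = "high"
    out[s == 0] = "neutral"
    return out


def genetic_load(state: SimState, patch_name: str) -> dict:
    """LoadReport entry for one patch: L = 1 − W_mean/W_max over females.

    W is the expected number of surviving offspring per female,
    fecundity × w(genotype); the fecundity factor cancels in the ratio.
    """
    patch = state.patches[patch_name]
    if patch.extinct or patch.size == 0:
        return {
            "generation": state.generation,
            "patch": patch_name,
            "n": 0,
            "extinct": True,
            "w_mean": np.nan,
            "w_max": np.nan,
            "load": np.nan,
        }
    females = patch.sex == FEMALE
    if not females.any():
        raise ValueError(f"patch {patch_name!r} has no females")
    w = state.params.fecundity_mean * genotype_fitness(
        patch.dosage[females], state.s, state.h, state.params.fitness_model
    )
    w_mean, w_max = float(w.mean()), float(w.max())
    entry = {
        "generation": state.generation,
        "patch": patch_name,
        "n": patch.size,
        "extinct": False,
        "w_mean": w_mean,
        "w_max": w_max,
        "load": 1.0 - w_mean / w_max if w_max > 0 else np.nan,
    }
    cats = locus_categories(state.s)
    for cat in ("neutral", "mild", "high"):
        cols = cats == cat
        sub = patch.dosage[:, cols]
        entry[f"mean_derived_alleles_{cat}"] = float(sub.sum(axis=1).mean())
        entry[f"mean_derived_homozygotes_{cat}"] = float((sub == 2).sum(axis=1).mean())
    return entry


# -- scenario runner -------------------------------------------------------


@dataclass
class SimulationResult:
    """Replicate load reports, extinction tally, and final/snapshot counts."""

    scenario: Scenario
    params: SelectionParams
    load_reports: pd.DataFrame
    extinctions: pd.DataFrame  # patch, n_extinct, n_replicates, rate
    # (replicate, generation, patch) -> (derived counts per locus, n individuals)
    snapshots: dict = field(default_factory=dict)
    s: dict = field(default_factory=dict)  # replicate -> s vector
    final_states: dict = field(default_factory=dict)  # replicate -> SimState

    def extinction_rate(self, patch: str) -> float:
        row = self.extinctions.loc[self.extinctions["patch"] == patch]
        if row.empty:
            raise KeyError(f"unknown patch {patch!r}")
        return float(row["rate"].iloc[0])

    def site_table(self, replicate: int, labels: dict) -> pd.DataFrame:
        """Build a load_stats-compatible site table from stored snapshots.

        ``labels`` maps a population label to a (generation, patch) snapshot
        key; the result has ``derived_count_<label>`` / ``n_called_<label>``
        columns plus per-locus s, h and effect category, with loci spread
        round-robin over pseudo-chromosome blocks for jackknifing.
        """
        s = self.s[replicate]
        n_loci = len(s)
        table = pd.DataFrame(
            {
                "chrom": [f"block{i % 10}" for i in range(n_loci)],
                "pos": np.arange(1, n_loci + 1) * 1000,
                "derived_allele": "ALT",
                "s": s,
                "h": np.where(s > 0, dominance_of(s, self.params.dominance_rate), 0.5),
                "category": locus_categories(s),
            }
        )
        for label, (generation, patch) in labels.items():
            counts, n_ind = self.snapshots[(replicate, generation, patch)]
            table[f"derived_count_{label}"] = counts
            table[f"n_called_{label}"] = n_ind
        return table

    def final_genotypes(self, replicate: int):
        """Final genotypes as (GenotypeTable, manifest) for the stats stage."""
        state = self.final_states[replicate]
        s = self.s[replicate]
        cols, names, manifest_rows = [], [], []
        for patch_name in state.extant_patches():
            patch = state.patches[patch_name]
            cols.append(patch.dosage.T)
            for i in range(patch.size):
                name = f"{patch_name}_ind{i + 1}"
                names.append(name)
                manifest_rows.append((name, patch_name, "simulated", "focal"))
        if not cols:
            raise ValueError("all patches extinct; no genotypes to export")
        dosage = np.hstack(cols).astype(np.int8)
        n_loci = dosage.shape[0]
        sites = pd.DataFrame(
            {
                "chrom": [f"block{i % 10}" for i in range(n_loci)],
                "pos": np.arange(1, n_loci + 1) * 1000,
                "ref": "A",
                "alt": "T",
                "s": s,
                "category": locus_categories(s),
            }
        )
        return GenotypeTable(sites, dosage, names), make_manifest(manifest_rows)


def _record_snapshot(result_snapshots, state, replicate):
    for name in state.extant_patches():
        patch = state.patches[name]
        result_snapshots[(replicate, state.generation, name)] = (
            patch.dosage.sum(axis=0).astype(np.int64),
            patch.size,
        )


def run_replicate(
    scenario: Scenario, params: SelectionParams, rng: np.random.Generator, replicate=0
):
    """Run one replicate; returns (state, reports, snapshots dict)."""
    state = initialize_burn_in(
        params,
        scenario.patches[scenario.burn_in_patch],
        rng,
        patch_name=scenario.burn_in_patch,
    )
    for name, k in scenario.patches.items():
        if name != scenario.burn_in_patch and k > 0:
            # patches extant from generation 0 besides the burn-in deme
            extra = initialize_burn_in(params, k, rng, patch_name=name)
            state.patches[name] = extra.patches[name]
    reports, snapshots = [], {}
    snapshot_set = set(scenario.snapshots)
    while state.generation < scenario.generations:
        for event in scenario.events_at(state.generation):
            if isinstance(event, SetK):
                if event.patch in state.patches:
                    state.patches[event.patch].k = event.k
            elif isinstance(event, Founding):
                try:
                    found_population(state, event)
                except ValueError as exc:
                    # cascade: a source went extinct before the event
                    logger.warning(
                        "founding of %s failed at generation %d: %s",
                        event.patch,
                        state.generation,
                        exc,
                    )
        if state.generation in snapshot_set:
            _record_snapshot(snapshots, state, replicate)
        if (state.generation in snapshot_set) or (
            scenario.report_every and state.generation % scenario.report_every == 0
        ):
            for name in state.patches:
                reports.append({**genetic_load(state, name), "replicate": replicate})
        advance_generation(state)
    if state.generation in snapshot_set:
        _record_snapshot(snapshots, state, replicate)
    for name in state.patches:
        reports.append({**genetic_load(state, name), "replicate": replicate})
    return state, reports, snapshots


def run_scenario(
    scenario: Scenario,
    params: SelectionParams,
    replicates: int = 1,
    seed: int = 0,
    keep_final_states: bool = True,
) -> SimulationResult:
    """Run the demographic program over independent replicates.

    Each replicate gets its own RNG substream derived from ``seed``, so
    results do not depend on execution order.  Extinction of a patch is a
    recorded outcome; the tally counts replicates in which a patch that was
    ever populated ends extinct.
    """
    all_reports, snapshots, s_by_rep, finals = [], {}, {}, {}
    # a patch is "in play" if it starts populated or is a founding target
    in_play = {name for name, k in scenario.patches.items() if k > 0}
    in_play |= {e.patch for e in scenario.events if isinstance(e, Founding)}
    extinct = {name: 0 for name in in_play}
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        state, reports, snaps = run_replicate(scenario, params, rng, rep)
        all_reports.extend(reports)
        snapshots.update(snaps)
        s_by_rep[rep] = state.s
        if keep_final_states:
            finals[rep] = state
        alive = set(state.extant_patches())
        for name in in_play:
            if name not in alive:
                extinct[name] += 1
    extinctions = pd.DataFrame(
        [
            {
                "patch": name,
                "n_extinct": extinct[name],
                "n_replicates": replicates,
                "rate": extinct[name] / replicates,
            }
            for name in sorted(in_play)
        ]
    )
    return SimulationResult(
        scenario=scenario,
        params=params,
        load_reports=pd.DataFrame(all_reports),
        extinctions=extinctions,
        snapshots=snapshots,
        s=s_by_rep,
        final_states=finals,
    )
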