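"""Coalescent simulation of microsatellite genotypes.

A :class:`Scenario` is a demographic event program — population splits,
admixtures and effective-size changes, all in generations before present
(generation time is one year, so years and generations coincide).  Genotypes
are produced locus by locus: an independent coalescent genealogy is drawn
with ``msprime`` under the scenario, and mutations under the generalized
stepwise model (GSM) are dropped on the branches.  A mutation changes the
repeat count by a geometrically distributed number of steps, up or down with
equal probability, reflected into a bounded allele range.

The same engine drives both the synthetic study fixture and the simulation
side of the ABC machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import yaml

from hydropop.io import MISSING, GenotypeTable, Locus, ValidationError


@dataclass
class MutationModel:
    """Generalized stepwise mutation model for microsatellites.

    Parameters
    ----------
    mean_rate
        Mean mutation rate per locus per generation (default 5e-4, the
        canonical microsatellite neighbourhood).
    rate_shape
        Shape of the Gamma distribution from which per-locus rates are drawn
        around ``mean_rate`` (shape 2 by default); ``None`` disables the
        spread (all loci share ``mean_rate``).
    p_geom
        Parameter of the geometric step-size distribution;
        ``P(step = k) = (1 - p) p^(k-1)``.  0 gives the strict single-step
        model (SMM).
    allele_range
        Number of contiguous allele states (reflecting boundaries).
    """

    mean_rate: float = 5e-4
    rate_shape: float | None = 2.0
    p_geom: float = 0.22
    allele_range: int = 40

    def __post_init__(self):
        if not (0 <= self.p_geom < 1):
            raise ValidationError("p_geom must be in [0, 1)")
        if self.allele_range < 2:
            raise ValidationError("allele_range must be >= 2")
        if self.mean_rate <= 0:
            raise ValidationError("mean_rate must be positive")

    def locus_rates(self, n_loci: int, rng: np.random.Generator) -> np.ndarray:
        if self.rate_shape is None:
            return np.full(n_loci, self.mean_rate)
        return rng.gamma(self.rate_shape, self.mean_rate / self.rate_shape, size=n_loci)

    def matrix_model(self) -> msprime.MatrixMutationModel:
        """The GSM as an msprime matrix mutation model on repeat counts."""
        key = (self.p_geom, self.allele_range)
        cached = _MATRIX_CACHE.get(key)
        if cached is not None:
            return cached
        R = self.allele_range
        alleles = [str(i) for i in range(R)]
        # geometric step sizes, truncated where the tail is negligible
        if self.p_geom == 0:
            ks = np.array([1])
            pk = np.array([1.0])
        else:
            kmax = max(R, int(np.ceil(np.log(1e-12) / np.log(self.p_geom))))
            ks = np.arange(1, kmax + 1)
            pk = (1 - self.p_geom) * self.p_geom ** (ks - 1)
            pk /= pk.sum()
        period = 2 * (R - 1) if R > 1 else 1
        i = np.arange(R)
        trans = np.zeros((R, R))
        for sign in (+1, -1):
            pos = np.mod(i[:, None] + sign * ks[None, :], period)
            j = np.where(pos < R, pos, period - pos)
            np.add.at(trans, (np.broadcast_to(i[:, None], j.shape), j),
                      0.5 * np.broadcast_to(pk[None, :], j.shape))
        root = np.zeros(R)
        root[R // 2] = 1.0
        model = msprime.MatrixMutationModel(
            alleles, root_distribution=root, transition_matrix=trans
        )
        if len(_MATRIX_CACHE) > 256:
            _MATRIX_CACHE.clear()
        _MATRIX_CACHE[key] = model
        return model


_MATRIX_CACHE: dict = {}


def _reflect(pos: int, R: int) -> int:
    """Fold an out-of-range state back into [0, R-1] (reflecting walls)."""
    period = 2 * (R - 1)
    if period == 0:
        return 0
    pos = pos % period
    if pos < 0:
        pos += period
    return pos if pos < R else period - pos


@dataclass
class NuisanceModel:
    """Genotyping artefacts: null alleles and randomly missing genotypes."""

    null_freq: dict = field(default_factory=dict)  # locus name -> frequency
    missing_rate: float = 0.0

    def __post_init__(self):
        for name, f in self.null_freq.items():
            if not (0 <= f <= 1):
                raise ValidationError(f"null_freq[{name}] outside [0, 1]")
        if not (0 <= self.missing_rate <= 1):
            raise ValidationError("missing_rate outside [0, 1]")


@dataclass
class SampledPop:
    name: str
    n: int  # diploid individuals sampled
    size: float  # effective size (diploid) in the most recent epoch
    time: float = 0.0  # sampling time, generations before present


@dataclass
class Event:
    kind: str  # "merge" | "admix" | "ne_change"
    time: float
    pop: str
    into: str | None = None  # merge target
    sources: tuple | None = None  # admixture (srcA, srcB)
    rate: float | None = None  # admixture proportion from sources[0]
    ne: float | None = None  # ne_change size


@dataclass
class Scenario:
    """Demographic event program for the coalescent engine.

    ``populations`` lists the sampled populations; ``ancestral`` maps
    additional (unsampled) population names to effective sizes.  Events are
    interpreted backward in time:

    * ``merge``: at time ``t`` lineages of ``pop`` join ``into`` (forward in
      time, ``pop`` was founded from ``into`` at ``t``);
    * ``admix``: at ``t`` lineages of ``pop`` move to ``sources[0]`` with
      probability ``rate`` and to ``sources[1]`` otherwise (forward in time,
      ``pop`` was founded as a mixture);
    * ``ne_change``: backward of time ``t`` the effective size of ``pop`` is
      ``ne`` (until an older ``ne_change`` overrides it) — two such events
      bracket a bottleneck.
    """

    populations: list = field(default_factory=list)  # of SampledPop
    ancestral: dict = field(default_factory=dict)  # name -> Ne
    events: list = field(default_factory=list)  # of Event

    # -- construction helpers ---------------------------------------------
    def add_population(self, name, n, size, time=0.0):
        self.populations.append(SampledPop(name, n, size, time))
        return self

    def merge(self, pop, into, time):
        self.events.append(Event("merge", time, pop, into=into))
        return self

    def admix(self, pop, src_a, src_b, rate, time):
        self.events.append(Event("admix", time, pop, sources=(src_a, src_b), rate=rate))
        return self

    def ne_change(self, pop, ne, time):
        self.events.append(Event("ne_change", time, pop, ne=ne))
        return self

    def bottleneck(self, pop, ne, start, end):
        """Effective size ``ne`` for ``pop`` between ``start`` and ``end``
        generations ago (start < end)."""
        if not start < end:
            raise ValidationError("bottleneck requires start < end")
        self.events.append(Event("ne_change", start, pop, ne=ne))
        return self

    # -- validation --------------------------------------------------------
    def all_pop_names(self):
        names = [p.name for p in self.populations] + list(self.ancestral)
        if len(set(names)) != len(names):
            raise ValidationError("duplicate population names in scenario")
        return names

    def validate(self):
        names = set(self.all_pop_names())
        for p in self.populations:
            if p.n < 0 or p.size < 1 or p.time < 0:
                raise ValidationError(f"population {p.name}: invalid n/size/time")
        for ev in self.events:
            if ev.time < 0:
                raise ValidationError(f"event at negative time {ev.time}")
            if ev.pop not in names:
                raise ValidationError(f"event references unknown population {ev.pop}")
            if ev.kind == "merge" and ev.into not in names:
                raise ValidationError(f"merge target {ev.into} unknown")
            if ev.kind == "admix":
                if not ev.sources or any(s not in names for s in ev.sources):
                    raise ValidationError("admixture sources unknown")
                if not (0 <= ev.rate <= 1):
                    raise ValidationError("admixture rate outside [0, 1]")
            if ev.kind == "ne_change" and (ev.ne is None or ev.ne < 1):
                raise ValidationError("ne_change requires ne >= 1")
        # every lineage must reach a single root looking backward
        active = {p.name for p in self.populations if p.n > 0}
        for ev in sorted(self.events, key=lambda e: e.time):
            if ev.kind == "merge" and ev.pop in active:
                active.discard(ev.pop)
                active.add(ev.into)
            elif ev.kind == "admix" and ev.pop in active:
                active.discard(ev.pop)
                active.update(ev.sources)
        if len(active) > 1:
            raise ValidationError(
                f"lineages cannot coalesce: populations {sorted(active)} never merge"
            )

    # -- msprime translation ----------------------------------------------
    def demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        for p in self.populations:
            dem.add_population(name=p.name, initial_size=p.size)
        for name, ne in self.ancestral.items():
            dem.add_population(name=name, initial_size=ne)
        eps = 1e-9
        for ev in sorted(self.events, key=lambda e: e.time):
            t = max(ev.time, eps)
            if ev.kind == "merge":
                dem.add_mass_migration(time=t, source=ev.pop, dest=ev.into, proportion=1.0)
            elif ev.kind == "admix":
                a, b = ev.sources
                dem.add_mass_migration(time=t, source=ev.pop, dest=a, proportion=ev.rate)
                dem.add_mass_migration(time=t + eps, source=ev.pop, dest=b, proportion=1.0)
            elif ev.kind == "ne_change":
                dem.add_population_parameters_change(
                    time=t, initial_size=ev.ne, population=ev.pop
                )
        dem.sort_events()
        return dem

    # -- config ------------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        pops = [
            SampledPop(p["name"], int(p.get("n", 0)), float(p["size"]), float(p.get("time", 0)))
            for p in d.get("populations", [])
        ]
        anc = {k: float(v) for k, v in d.get("ancestral", {}).items()}
        events = []
        for e in d.get("events", []):
            events.append(
                Event(
                    e["kind"],
                    float(e["time"]),
                    e["pop"],
                    into=e.get("into"),
                    sources=tuple(e["sources"]) if "sources" in e else None,
                    rate=float(e["rate"]) if "rate" in e else None,
                    ne=float(e["ne"]) if "ne" in e else None,
                )
            )
        return cls(populations=pops, ancestral=anc, events=events)

    @classmethod
    def from_config(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def mutation_model_from_config(path) -> MutationModel:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return MutationModel(
        mean_rate=float(d.get("mean_rate", 5e-4)),
        rate_shape=d.get("rate_shape", 2.0),
        p_geom=float(d.get("p_geom", 0.22)),
        allele_range=int(d.get("allele_range", 40)),
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_repeat_counts(
    scenario: Scenario,
    mut: MutationModel,
    n_loci: int,
    seed: int,
    locus_rates=None,
) -> np.ndarray:
    """Simulate repeat-count genotypes, shape (n_individuals, n_loci, 2).

    One independent genealogy per locus; GSM mutations on branches.  The
    individual order follows the scenario's population list.
    """
    scenario.validate()
    rng = np.random.default_rng(seed)
    dem = scenario.demography()
    samples = [
        msprime.SampleSet(p.n, population=p.name, time=p.time)
        for p in scenario.populations
        if p.n > 0
    ]
    n_ind = sum(p.n for p in scenario.populations)
    if locus_rates is None:
        locus_rates = mut.locus_rates(n_loci, rng)
    model = mut.matrix_model()
    root_state = mut.allele_range // 2
    out = np.empty((n_ind, n_loci, 2), dtype=np.int32)
    anc_seed = int(rng.integers(1, 2**31 - 1))
    replicates = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=2,
        sequence_length=1,
        discrete_genome=True,
        num_replicates=n_loci,
        random_seed=anc_seed,
        record_provenance=False,
    )
    mut_seeds = rng.integers(1, 2**31 - 1, size=n_loci)
    for j, ts in enumerate(replicates):
        mts = msprime.sim_mutations(
            ts, rate=float(locus_rates[j]), model=model, random_seed=int(mut_seeds[j]),
            record_provenance=False,
        )
        states = np.full(2 * n_ind, root_state, dtype=np.int32)
        for var in mts.variants():
            alleles = np.array([int(a) for a in var.alleles], dtype=np.int32)
            states = alleles[var.genotypes]
            break  # single site
        out[:, j, 0] = states[0::2]
        out[:, j, 1] = states[1::2]
    return out


def simulate_coalescent(
    scenario: Scenario,
    mut: MutationModel,
    n_loci: int,
    seed: int,
    loci=None,
    size_offsets=None,
) -> GenotypeTable:
    """Simulate a diploid :class:`GenotypeTable` under a scenario.

    Allele sizes are reported in base pairs:
    ``size = offset + repeat_count * motif_length``.  Loci default to
    dinucleotide repeats named ``L01..`` with offset 100 bp.  Deterministic
    given ``seed``.
    """
    if loci is None:
        loci = [Locus(f"L{j + 1:02d}", motif_length=2) for j in range(n_loci)]
    if len(loci) != n_loci:
        raise ValidationError("loci list length must equal n_loci")
    if size_offsets is None:
        size_offsets = [100] * n_loci
    repeats = simulate_repeat_counts(scenario, mut, n_loci, seed)
    calls = np.empty_like(repeats)
    for j, loc in enumerate(loci):
        calls[:, :, :][:, j, :] = size_offsets[j] + repeats[:, j, :] * loc.motif_length
    individuals, pops = [], []
    for p in scenario.populations:
        for i in range(p.n):
            individuals.append(f"{p.name}_{i + 1:03d}")
            pops.append(p.name)
    return GenotypeTable(individuals, loci, calls, pops)


def apply_nuisance(table: GenotypeTable, nuisance: NuisanceModel, seed: int) -> GenotypeTable:
    """Overlay null alleles and random missingness on a genotype table.

    Each allele copy independently fails to amplify with the locus' null
    frequency; a heterozygote with one null shows as an apparent homozygote
    for the visible allele, a null/null genotype becomes missing.  An
    additional fraction ``missing_rate`` of genotypes is then blanked at
    random.
    """
    rng = np.random.default_rng(seed)
    calls = table.calls.copy()
    n, L, _ = calls.shape
    for j, loc in enumerate(table.loci):
        f = nuisance.null_freq.get(loc.name, 0.0)
        if f <= 0:
            continue
        nulled = rng.random((n, 2)) < f
        g = calls[:, j, :]
        present = g[:, 0] != MISSING
        both = nulled.all(axis=1) & present
        one = (nulled.sum(axis=1) == 1) & present
        # visible allele duplicated into an apparent homozygote
        visible = np.where(nulled[:, 0], g[:, 1], g[:, 0])
        g[one, 0] = visible[one]
        g[one, 1] = visible[one]
        g[both] = MISSING
        calls[:, j, :] = g
    if nuisance.missing_rate > 0:
        drop = rng.random((n, L)) < nuisance.missing_rate
        calls[drop] = MISSING
    return GenotypeTable(table.individuals, table.loci, calls, table.populations)
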