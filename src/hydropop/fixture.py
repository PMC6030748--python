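"""Synthetic study fixture: a 27-population, three-watershed dataset.

The generator emulates the sampling design of a central-European bitterling
survey spanning the Black Sea (Danube), North Sea (Elbe + Rhine) and Baltic
Sea (Oder + Vistula) drainages: 688 diploids genotyped at 12 microsatellite
loci across 27 populations, plus 83 mtDNA control sequences (1124 bp) from
26 sites falling into two deeply split lineages with a star-like western
haplogroup.

Two populations carry the histories the downstream inference machinery is
meant to detect:

* ``ELB3`` (the Sázava sample) is an admixture of the Czech Elbe stem and
  the western-Morava stem 229 generations ago, with 61.3 % of its ancestry
  from the Morava side and a founding bottleneck of Ne = 69 lasting 6
  generations;
* ``ODR1``–``ODR3`` (the Czech Oder samples) descend from the northern
  Morava stem via a translocation 130 generations ago through a bottleneck
  of Ne = 50 — so they sit in the Baltic watershed but carry Danube genes.

Two loci carry null alleles at frequencies 0.069 (``Rser04``) and 0.079
(``Rser09``), two are hyper-variable (``Rser04``, ``Rser13``), and ~3.9 % of
genotypes are missing at random, mirroring a realistic genotyping success of
~96 %.
"""

from __future__ import annotations

import numpy as np

from hydropop.io import GenotypeTable, GroupingScheme, Locus, SequenceAlignment
from hydropop.simulate import (
    MutationModel,
    NuisanceModel,
    SampledPop,
    Scenario,
    apply_nuisance,
    simulate_coalescent,
)

# population -> (sample size, recent Ne, founding stem, split time) ---------
# sample sizes follow the study design (total 688)
_POPS = {
    "DAN1": (45, 1500, "MORAVA_N", 250),
    "DAN2": (34, 1500, "MORAVA_N", 200),
    "DAN3": (15, 1000, "DANUBE", 800),
    "DAN4": (24, 1200, "MORAVA_N", 180),
    "DAN5": (24, 1200, "MORAVA_N", 160),
    "DAN6": (25, 1000, "MORAVA_N", 220),
    "DAN7": (23, 1000, "MORAVA_N", 240),
    "DAN8": (24, 1000, "MORAVA_W", 260),
    "DAN9": (9, 600, "MORAVA_W", 300),
    "DAN10": (23, 800, "MORAVA_W", 280),
    "DAN11": (21, 800, "DANUBE", 1000),
    "DAN12": (25, 800, "DANUBE", 1000),
    "RHI1": (27, 1000, "RHINE", 500),
    "RHI2": (25, 800, "RHINE", 700),
    "RHI3": (22, 1000, "RHINE", 450),
    "NET": (16, 600, "RHINE", 800),
    "ELB1": (46, 1500, "CZELBE", 200),
    "ELB2": (22, 1000, "CZELBE", 250),
    "ELB4": (18, 800, "CZELBE", 300),
    "ODR4": (22, 800, "BALTIC", 700),
    "VIS1": (29, 800, "BALTIC", 600),
    "VIS2": (24, 800, "BALTIC", 650),
}

# the two focal histories, parameterized by the posterior point estimates
# the inference stage is expected to recover
SAZAVA_ADMIX_TIME = 229.0
SAZAVA_ADMIX_RATE = 0.613  # ancestry fraction from the Morava (Danube) side
SAZAVA_BOTTLENECK_NE = 69.0
SAZAVA_BOTTLENECK_DUR = 6.0
CZODER_FOUNDING_TIME = 130.0
CZODER_BOTTLENECK_NE = 50.0
CZODER_BOTTLENECK_DUR = 10.0

_STEMS = {
    "DANUBE": 8000,
    "MORAVA_N": 5000,
    "MORAVA_W": 4000,
    "ELBE": 4000,
    "CZELBE": 3000,
    "RHINE": 3000,
    "BALTIC": 3000,
    "CZODER_ANC": 1000,
}

WATERSHED_OF = {
    **{p: "black" for p in _POPS if p.startswith("DAN")},
    **{p: "north" for p in ("RHI1", "RHI2", "RHI3", "NET", "ELB1", "ELB2", "ELB4")},
    "ELB3": "north",
    **{p: "baltic" for p in ("ODR1", "ODR2", "ODR3", "ODR4", "VIS1", "VIS2")},
    "ITA": "mediterranean",
}

#: populations flagged as hydrographically mismatched (admixed / translocated)
MISMATCHED = ["ELB3", "ODR1", "ODR2", "ODR3"]

#: the grouping used for ABC: label -> member populations
ABC_GROUPS = {
    "SAZAVA": ["ELB3"],
    "CZELBE": ["ELB1", "ELB2", "ELB4"],
    "WMORAV": ["DAN8", "DAN9", "DAN10"],
    "CZODER": ["ODR1", "ODR2", "ODR3"],
    "POLRIV": ["ODR4", "VIS1", "VIS2"],
    "NMORAV": ["DAN1", "DAN2", "DAN4", "DAN5", "DAN6", "DAN7"],
}

# sampling-site coordinates (decimal degrees) for distance computations
_COORDS = {
    "DAN1": (48.780, 17.016), "DAN2": (48.693, 16.999), "DAN3": (47.883, 17.500),
    "DAN4": (49.029, 17.393), "DAN5": (49.046, 17.468), "DAN6": (49.340, 17.345),
    "DAN7": (49.433, 17.339), "DAN8": (49.041, 16.616), "DAN9": (49.127, 16.330),
    "DAN10": (49.209, 15.991), "DAN11": (48.899, 22.391), "DAN12": (47.364, 19.823),
    "RHI1": (51.788, 6.371), "RHI2": (50.283, 8.796), "RHI3": (51.785, 6.334),
    "NET": (51.626, 4.586), "ELB1": (50.297, 14.481), "ELB2": (50.101, 15.158),
    "ELB3": (49.841, 14.681), "ELB4": (50.033, 15.616), "ODR1": (49.890, 18.307),
    "ODR2": (49.753, 18.282), "ODR3": (49.617, 17.920), "ODR4": (51.031, 16.999),
    "VIS1": (52.617, 18.478), "VIS2": (52.550, 19.583), "ITA": (45.403, 8.740),
}

# locus panel: names, motif lengths, per-locus mutation rates, size offsets.
# Rser04/Rser13 hyper-variable; Rser11 a tetranucleotide; offsets arbitrary
# but distinct so allele-size ranges do not collide across loci.
_LOCI = [
    # (name, motif, rate, offset)
    ("Rser01", 2, 4.0e-4, 96),
    ("Rser02", 2, 5.0e-4, 104),
    ("Rser03", 2, 3.0e-4, 112),
    ("Rser04", 2, 5.0e-3, 120),
    ("Rser05", 2, 6.0e-4, 128),
    ("Rser06", 2, 4.5e-4, 136),
    ("Rser07", 2, 3.5e-4, 144),
    ("Rser09", 2, 5.5e-4, 152),
    ("Rser10", 2, 5.0e-4, 160),
    ("Rser11", 4, 2.5e-4, 168),
    ("Rser12", 2, 4.0e-4, 176),
    ("Rser13", 2, 5.0e-3, 184),
]

NULL_ALLELE_LOCI = {"Rser04": 0.069, "Rser09": 0.079}
MISSING_RATE = 0.039
REDUCED_LOCUS_SET = [n for n, *_ in _LOCI if n not in ("Rser04", "Rser09", "Rser13")]

# mtDNA sequences per population (total 83 over 26 sites; "LICH" has mtDNA only)
_CYTB_N = {
    "DAN2": 1, "DAN3": 4, "DAN4": 2, "DAN5": 2, "DAN6": 2, "DAN7": 2,
    "DAN8": 2, "DAN9": 2, "DAN10": 2, "DAN11": 5, "DAN12": 5,
    "RHI1": 5, "RHI2": 5, "RHI3": 3, "NET": 5,
    "ELB1": 3, "ELB2": 3, "ELB3": 3, "ELB4": 3,
    "ODR1": 3, "ODR2": 3, "ODR3": 3, "ODR4": 5,
    "VIS1": 3, "ITA": 4, "LICH": 3,
}
_EASTERN_MT_POPS = {"VIS1", "ODR4", "LICH"}
_MT_LENGTH = 1124
_MT_LINEAGE_DIFFS = 14  # fixed substitutions separating the two lineages


def study_scenario() -> Scenario:
    """The demographic event program behind the fixture genotypes."""
    sc = Scenario()
    for name, (n, ne, _, _) in _POPS.items():
        sc.add_population(name, n, ne)
    sc.add_population("ELB3", 26, 800)
    for name in ("ODR1", "ODR2", "ODR3"):
        sc.add_population(name, {"ODR1": 36, "ODR2": 27, "ODR3": 22}[name], 500)
    sc.add_population("ITA", 34, 300)
    sc.ancestral = dict(_STEMS)
    for name, (_, _, stem, t) in _POPS.items():
        sc.merge(name, stem, t)
    # stems
    sc.merge("MORAVA_N", "DANUBE", 1500)
    sc.merge("MORAVA_W", "DANUBE", 1500)
    sc.merge("CZELBE", "ELBE", 1200)
    sc.merge("RHINE", "ELBE", 2000)
    sc.merge("ELBE", "DANUBE", 3000)
    sc.merge("BALTIC", "DANUBE", 6000)
    # SAZAVA: admixture + founding bottleneck
    sc.ne_change("ELB3", SAZAVA_BOTTLENECK_NE, SAZAVA_ADMIX_TIME - SAZAVA_BOTTLENECK_DUR)
    sc.admix("ELB3", "MORAVA_W", "CZELBE", SAZAVA_ADMIX_RATE, SAZAVA_ADMIX_TIME)
    # CZODER: translocation from the northern Morava stem through a bottleneck
    for name in ("ODR1", "ODR2", "ODR3"):
        sc.merge(name, "CZODER_ANC", 60)
    sc.ne_change("CZODER_ANC", CZODER_BOTTLENECK_NE,
                 CZODER_FOUNDING_TIME - CZODER_BOTTLENECK_DUR)
    sc.merge("CZODER_ANC", "MORAVA_N", CZODER_FOUNDING_TIME)
    # ITA: recent introduction with a founder bottleneck
    sc.ne_change("ITA", 25, 70)
    sc.merge("ITA", "DANUBE", 80)
    sc.validate()
    return sc


def study_loci():
    return [Locus(name, motif_length=m) for name, m, _, _ in _LOCI]


def study_grouping() -> GroupingScheme:
    pops = list(_POPS) + ["ELB3", "ODR1", "ODR2", "ODR3", "ITA"]
    # keep a stable, design-ordered population list
    order = [
        "DAN1", "DAN2", "DAN3", "DAN4", "DAN5", "DAN6", "DAN7", "DAN8", "DAN9",
        "DAN10", "DAN11", "DAN12", "RHI1", "RHI2", "RHI3", "NET", "ELB1",
        "ELB2", "ELB3", "ELB4", "ODR1", "ODR2", "ODR3", "ODR4", "VIS1",
        "VIS2", "ITA",
    ]
    assert sorted(order) == sorted(pops)
    return GroupingScheme(
        populations=order,
        group_of={p: WATERSHED_OF[p] for p in order},
        coords={p: _COORDS[p] for p in order},
    )


def make_study_fixture(seed: int):
    """Generate the full study fixture.

    Returns
    -------
    (GenotypeTable, GroupingScheme, SequenceAlignment)
        688 genotyped individuals from 27 populations at 12 loci (with null
        alleles and missing data overlaid), the population/watershed/
        coordinate scheme, and the 83-sequence mtDNA alignment.
        Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sc = study_scenario()
    mut = MutationModel(mean_rate=5e-4, rate_shape=None, p_geom=0.22, allele_range=50)
    loci = study_loci()
    rates = np.array([r for _, _, r, _ in _LOCI])
    offsets = [o for _, _, _, o in _LOCI]
    from hydropop.simulate import simulate_repeat_counts

    repeats = simulate_repeat_counts(sc, mut, len(loci), int(rng.integers(1, 2**31 - 1)),
                                     locus_rates=rates)
    calls = np.empty_like(repeats)
    for j, loc in enumerate(loci):
        calls[:, j, :] = offsets[j] + repeats[:, j, :] * loc.motif_length
    individuals, pops = [], []
    for p in sc.populations:
        for i in range(p.n):
            individuals.append(f"{p.name}_{i + 1:03d}")
            pops.append(p.name)
    table = GenotypeTable(individuals, loci, calls, pops)
    nuis = NuisanceModel(null_freq=dict(NULL_ALLELE_LOCI), missing_rate=MISSING_RATE)
    table = apply_nuisance(table, nuis, int(rng.integers(1, 2**31 - 1)))
    grouping = study_grouping()
    aln = simulate_mtdna(int(rng.integers(1, 2**31 - 1)))
    return table, grouping, aln


def _three_group_scenario(sizes, ne, t1, t_anc, origin, rate=None,
                          nb=None, db=None, focal=None, sources=None):
    """Backbone for the origin-of-a-focal-group scenario families.

    Two source groups split at ``t_anc``; the focal group originates at
    ``t1`` either from one source (split) or from both (admixture with
    ancestry fraction ``rate`` from ``sources[0]``), optionally through a
    founding bottleneck of size ``nb`` lasting ``db`` generations.
    """
    focal, src_a, src_b = focal
    sc = Scenario()
    sc.add_population(focal, sizes[focal], ne[focal])
    sc.add_population(src_a, sizes[src_a], ne[src_a])
    sc.add_population(src_b, sizes[src_b], ne[src_b])
    sc.ancestral = {"ANC": ne["ANC"]}
    if nb is not None and db and db > 0 and t1 - db > 0:
        sc.ne_change(focal, max(nb, 2), t1 - db)
    if origin == "admix":
        sc.admix(focal, sources[0], sources[1], rate, t1)
    else:
        sc.merge(focal, origin, t1)
    sc.merge(src_a, "ANC", t_anc)
    sc.merge(src_b, "ANC", t_anc)
    return sc


def _family(name, focal, src_a, src_b, sizes, origin, sources=None,
            with_rate=False):
    from hydropop.abc import ScenarioFamily

    priors = {
        "ne_focal": (100, 5000),
        "ne_a": (500, 20000),
        "ne_b": (500, 20000),
        "ne_anc": (500, 20000),
        "t1": (10, 1500),
        "t_anc": (500, 20000),
        "nb": (2, 100),
        "db": (0, 30),
    }
    if with_rate:
        priors["rate"] = (0.05, 0.95)

    def builder(p):
        ne = {focal: p["ne_focal"], src_a: p["ne_a"], src_b: p["ne_b"],
              "ANC": p["ne_anc"]}
        return _three_group_scenario(
            sizes, ne, p["t1"], p["t_anc"], origin,
            rate=p.get("rate"), nb=p["nb"], db=p["db"],
            focal=(focal, src_a, src_b), sources=sources,
        )

    return ScenarioFamily(name, priors, builder,
                          constraints=[lambda p: p["t1"] < p["t_anc"]])


def sazava_families(sizes=None):
    """Three candidate origins of the Sázava (ELB3) sample: admixture of the
    Czech Elbe and western Morava groups, or a pure split from either."""
    sizes = sizes or {"SAZAVA": 26, "CZELBE": 86, "WMORAV": 56}
    args = ("SAZAVA", "CZELBE", "WMORAV", sizes)
    return [
        _family("admixture", *args, origin="admix",
                sources=("WMORAV", "CZELBE"), with_rate=True),
        _family("from_CZELBE", *args, origin="CZELBE"),
        _family("from_WMORAV", *args, origin="WMORAV"),
    ]


def czoder_families(sizes=None):
    """Three candidate origins of the Czech Oder group: translocation from
    the northern Morava (Danube) group, local Baltic origin from the Polish
    rivers group, or admixture of both."""
    sizes = sizes or {"CZODER": 85, "NMORAV": 175, "POLRIV": 75}
    args = ("CZODER", "NMORAV", "POLRIV", sizes)
    return [
        _family("from_NMORAV", *args, origin="NMORAV"),
        _family("from_POLRIV", *args, origin="POLRIV"),
        _family("admixture", *args, origin="admix",
                sources=("NMORAV", "POLRIV"), with_rate=True),
    ]


def simulate_mtdna(seed: int) -> SequenceAlignment:
    """Two-lineage mtDNA alignment under infinite-sites mutation.

    The western lineage is star-like: a common central haplotype from which
    most derived haplotypes differ by one or two private substitutions.  The
    eastern lineage (Polish Baltic sites) is separated by a fixed block of
    substitutions and carries a couple of internal haplotypes.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    anc = rng.integers(0, 4, size=_MT_LENGTH)
    # infinite sites: each mutation hits a fresh site
    free_sites = rng.permutation(_MT_LENGTH).tolist()

    def mutate(seq, n_sub):
        seq = seq.copy()
        for _ in range(n_sub):
            s = free_sites.pop()
            seq[s] = (seq[s] + rng.integers(1, 4)) % 4
        return seq

    west_core = anc
    east_core = mutate(anc, _MT_LINEAGE_DIFFS)
    # two internal eastern sub-haplotypes
    east_sub = [east_core, mutate(east_core, 2), mutate(east_core, 3)]
    records, population_of = {}, {}
    k = 0
    for pop, n in _CYTB_N.items():
        for i in range(n):
            k += 1
            name = f"{pop}_mt{i + 1}"
            if pop in _EASTERN_MT_POPS:
                core = east_sub[rng.integers(0, len(east_sub))]
                seq = mutate(core, rng.integers(0, 2))
            else:
                # star-like: mostly the central haplotype, few private tips
                if rng.random() < 0.55:
                    seq = west_core.copy()
                else:
                    seq = mutate(west_core, rng.integers(1, 3))
            records[name] = "".join(bases[seq])
            population_of[name] = pop
    return SequenceAlignment(records, population_of)
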