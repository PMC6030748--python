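"""Core data model and file formats.

Genotypes are diploid microsatellite allele-size calls (base pairs) stored in
a dense integer array; mtDNA is an equal-length nucleotide alignment; the
population/group hierarchy plus geography lives in a :class:`GroupingScheme`.

Interchange formats are Genepop (2- or 3-digit allele codes) for genotypes,
FASTA for sequences and delimited text for metadata.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Sentinel for a missing (whole-genotype) call.
MISSING: int = -1

_ALPHABET = set("ACGTN-")


class GenepopParseError(ValueError):
    """Raised when a Genepop file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when data violate a structural invariant."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus.

    Parameters
    ----------
    name
        Locus identifier.
    motif_length
        Length of the repeat unit in base pairs (e.g. 2 for a dinucleotide).
    allele_unit
        Unit in which allele calls are expressed; ``"base_pairs"`` (default)
        or ``"repeat_units"``.
    """

    name: str
    motif_length: int = 2
    allele_unit: str = "base_pairs"

    def __post_init__(self):
        if self.motif_length < 1:
            raise ValidationError(f"locus {self.name}: motif_length must be >= 1")
        if self.allele_unit not in ("base_pairs", "repeat_units"):
            raise ValidationError(f"locus {self.name}: bad allele_unit {self.allele_unit!r}")


class GenotypeTable:
    """Diploid genotypes for a set of individuals at a set of loci.

    Allele calls are stored as integer allele sizes (base pairs by
    convention); a missing genotype is ``(MISSING, MISSING)``.  Statistics
    that need repeat counts (R_ST, stepwise-mutation summaries) convert via
    the per-locus motif length, using the minimum observed allele size as
    offset.

    Parameters
    ----------
    individuals : sequence of str
        Unique individual identifiers, in order.
    loci : sequence of Locus
    calls : ndarray of shape (n_individuals, n_loci, 2)
        Allele sizes; ``MISSING`` marks a missing genotype (both slots).
    populations : sequence of str
        Population label per individual.
    """

    def __init__(self, individuals, loci, calls, populations):
        self.individuals = list(individuals)
        self.loci = list(loci)
        calls = np.asarray(calls, dtype=np.int32)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        self.calls = calls
        self.populations = np.asarray(populations, dtype=object)
        if len(self.populations) != len(self.individuals):
            raise ValidationError("populations length mismatch")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("duplicate individual identifiers")
        self._validate_calls()

    def _validate_calls(self):
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValidationError("half-missing genotype calls are not representable")
        bad = (self.calls != MISSING) & (self.calls <= 0)
        if bad.any():
            raise ValidationError("allele sizes must be positive integers")
        # per-locus congruence modulo motif length (offsets differ per locus)
        for j, loc in enumerate(self.loci):
            if loc.allele_unit != "base_pairs" or loc.motif_length == 1:
                continue
            sizes = self.calls[:, j, :]
            sizes = sizes[sizes != MISSING]
            if sizes.size == 0:
                continue
            residues = np.unique(sizes % loc.motif_length)
            if residues.size > 1:
                offenders = sorted(np.unique(sizes).tolist())
                raise ValidationError(
                    f"locus {loc.name}: allele sizes {offenders} not congruent "
                    f"modulo motif length {loc.motif_length}"
                )

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self):
        return [loc.name for loc in self.loci]

    def population_labels(self):
        """Population labels in order of first appearance."""
        seen = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def population_of(self, individual: str) -> str:
        return self.populations[self.individuals.index(individual)]

    # -- views -------------------------------------------------------------
    def pop_mask(self, population) -> np.ndarray:
        if isinstance(population, str):
            population = [population]
        return np.isin(self.populations, list(population))

    def subset(self, populations=None, loci=None, individuals_mask=None) -> "GenotypeTable":
        """Return a new table restricted to given populations and/or loci."""
        mask = np.ones(self.n_individuals, dtype=bool)
        if populations is not None:
            mask &= self.pop_mask(populations)
        if individuals_mask is not None:
            mask &= individuals_mask
        if loci is None:
            locus_idx = np.arange(self.n_loci)
            loci_out = self.loci
        else:
            name_to_idx = {loc.name: j for j, loc in enumerate(self.loci)}
            locus_idx = np.array([name_to_idx[n] for n in loci])
            loci_out = [self.loci[j] for j in locus_idx]
        return GenotypeTable(
            [ind for ind, m in zip(self.individuals, mask) if m],
            loci_out,
            self.calls[np.ix_(mask, locus_idx)],
            self.populations[mask],
        )

    def relabel_groups(self, group_of: dict) -> "GenotypeTable":
        """Return a copy whose population labels are mapped through ``group_of``."""
        return GenotypeTable(
            self.individuals,
            self.loci,
            self.calls,
            [group_of[p] for p in self.populations],
        )

    # -- allele coding -----------------------------------------------------
    def locus_codes(self, j: int, mask=None):
        """Integer-coded alleles at locus ``j``.

        Returns ``(codes, sizes)`` where ``codes`` has shape (n, 2) with -1
        for missing, and ``sizes[k]`` is the allele size of code ``k``
        (sorted ascending).
        """
        g = self.calls[:, j, :] if mask is None else self.calls[mask, j, :]
        sizes = np.unique(g[g != MISSING])
        codes = np.full(g.shape, -1, dtype=np.int32)
        if sizes.size:
            obs = g != MISSING
            codes[obs] = np.searchsorted(sizes, g[obs])
        return codes, sizes

    def repeat_units(self, j: int, sizes=None):
        """Convert allele sizes at locus ``j`` to integer repeat counts.

        The offset is the minimum observed allele size at the locus, so the
        smallest allele maps to repeat count 0; only differences matter for
        every statistic defined on repeat counts.
        """
        loc = self.loci[j]
        if sizes is None:
            g = self.calls[:, j, :]
            sizes = np.unique(g[g != MISSING])
        sizes = np.asarray(sizes)
        if loc.allele_unit == "repeat_units":
            return sizes - (sizes.min() if sizes.size else 0)
        if sizes.size == 0:
            return sizes
        offset = int(sizes.min())
        units, rem = np.divmod(sizes - offset, loc.motif_length)
        if np.any(rem != 0):
            raise ValidationError(
                f"locus {loc.name}: allele sizes not congruent modulo "
                f"{loc.motif_length}"
            )
        return units

    def allele_counts(self, j: int, population=None):
        """(sizes, counts) of alleles at locus ``j``, optionally per population."""
        mask = None if population is None else self.pop_mask(population)
        g = self.calls[:, j, :] if mask is None else self.calls[mask, j, :]
        obs = g[g != MISSING]
        sizes, counts = np.unique(obs, return_counts=True)
        return sizes, counts

    def __eq__(self, other):
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and list(self.populations) == list(other.populations)
            and np.array_equal(_sorted_calls(self.calls), _sorted_calls(other.calls))
        )

    def __repr__(self):
        return (
            f"<GenotypeTable {self.n_individuals} individuals x "
            f"{self.n_loci} loci, {len(self.population_labels())} populations>"
        )


def _sorted_calls(calls):
    # genotypes are unordered pairs; canonicalize before comparison
    return np.sort(calls, axis=2)


@dataclass
class GroupingScheme:
    """Population -> group hierarchy plus geography.

    Parameters
    ----------
    populations : list of str
    group_of : dict
        Population label -> group label (e.g. watershed).
    coords : dict, optional
        Population -> (latitude, longitude) in decimal degrees.
    distances : DataFrame, optional
        Symmetric population x population distance matrix in km; when absent
        and coordinates are given, great-circle distances are computed on
        demand.
    distance_kind : str
        ``"euclidean"`` (great-circle) or ``"hydrographic"`` — a tag carried
        into reports.
    """

    populations: list
    group_of: dict = field(default_factory=dict)
    coords: dict = field(default_factory=dict)
    distances: "object" = None
    distance_kind: str = "euclidean"

    def __post_init__(self):
        if len(set(self.populations)) != len(self.populations):
            raise ValidationError("duplicate population labels")
        if self.distances is not None:
            d = np.asarray(self.distances, dtype=float)
            if d.shape != (len(self.populations),) * 2:
                raise ValidationError("distance matrix shape mismatch")
            if not np.allclose(d, d.T):
                raise ValidationError("distance matrix not symmetric")
            if not np.allclose(np.diag(d), 0):
                raise ValidationError("distance matrix diagonal not zero")

    def groups(self):
        seen = {}
        for p in self.populations:
            g = self.group_of.get(p)
            if g is not None:
                seen.setdefault(g, []).append(p)
        return seen

    def n_pairs(self) -> int:
        n = len(self.populations)
        return n * (n - 1) // 2

    def pairs(self):
        pops = self.populations
        return [(pops[i], pops[j]) for i in range(len(pops)) for j in range(i + 1, len(pops))]

    def distance(self, a: str, b: str) -> float:
        ia, ib = self.populations.index(a), self.populations.index(b)
        if self.distances is not None:
            return float(np.asarray(self.distances, dtype=float)[ia, ib])
        if a in self.coords and b in self.coords:
            return great_circle_km(self.coords[a], self.coords[b])
        raise ValidationError(f"no distance available for pair ({a}, {b})")

    def distance_matrix(self) -> np.ndarray:
        n = len(self.populations)
        if self.distances is not None:
            return np.asarray(self.distances, dtype=float)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = great_circle_km(
                    self.coords[self.populations[i]], self.coords[self.populations[j]]
                )
        return d


def great_circle_km(coord_a, coord_b, radius_km: float = 6371.0088) -> float:
    """Haversine great-circle distance between two (lat, lon) pairs in km."""
    lat1, lon1 = map(math.radians, coord_a)
    lat2, lon2 = map(math.radians, coord_b)
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * radius_km * math.asin(min(1.0, math.sqrt(h)))


class SequenceAlignment:
    """Equal-length nucleotide alignment with population membership."""

    def __init__(self, records: dict, population_of: dict | None = None):
        if not records:
            raise ValidationError("empty alignment")
        self.records = {str(k): str(v).upper() for k, v in records.items()}
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise ValidationError(f"unequal sequence lengths: {sorted(lengths)}")
        self.length = lengths.pop()
        for name, seq in self.records.items():
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValidationError(f"sequence {name}: illegal characters {sorted(bad)}")
        self.population_of = dict(population_of or {})

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def __repr__(self):
        return f"<SequenceAlignment {self.n_sequences} sequences x {self.length} sites>"


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def _decode_genepop_call(tok: str, line_no: int):
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise GenepopParseError(
            f"line {line_no}: allele code {tok!r} is neither 4 nor 6 digits"
        )
    try:
        a1, a2 = int(tok[:w]), int(tok[w:])
    except ValueError as exc:
        raise GenepopParseError(f"line {line_no}: non-numeric allele code {tok!r}") from exc
    if a1 == 0 or a2 == 0:
        return (MISSING, MISSING)
    return (a1, a2)


def read_genepop(path, loci=None, pop_names=None) -> GenotypeTable:
    """Read a Genepop (.gen) file.

    Parameters
    ----------
    path : path or file-like
    loci : sequence of Locus, optional
        Locus definitions (motif lengths).  When omitted all loci default to
        motif length 2 with allele-size congruence checks disabled
        (``motif_length=1``).
    pop_names : sequence of str, optional
        Explicit population labels, overriding the labels derived from each
        block's first individual identifier (common Genepop practice uses the
        identifier of the first — here, last token of the line preceding the
        block is unreliable, so the first individual's identifier token is
        used).

    Both the 2-digit and 3-digit allele encodings are accepted; ``00``/``000``
    is the missing code.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file")
    # line 1: title. Then locus names until first "pop".
    locus_names = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no 'Pop' separator found")
    if loci is None:
        loci = [Locus(n, motif_length=1) for n in locus_names]
    else:
        loci = list(loci)
        if [l.name for l in loci] != locus_names and len(loci) == len(locus_names):
            loci = [
                Locus(n, motif_length=l.motif_length, allele_unit=l.allele_unit)
                for n, l in zip(locus_names, loci)
            ]
        elif len(loci) != len(locus_names):
            raise GenepopParseError(
                f"{len(locus_names)} loci in file but {len(loci)} Locus definitions given"
            )
    n_loci = len(loci)
    individuals, pops, rows = [], [], []
    pop_idx = -1
    current_pop_label = None
    for line_no in range(i, len(lines)):
        raw = lines[line_no]
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            current_pop_label = None
            continue
        if "," not in line:
            raise GenepopParseError(f"line {line_no + 1}: expected 'id , genotypes' row")
        ident, geno = line.split(",", 1)
        ident = ident.strip()
        toks = geno.split()
        if len(toks) != n_loci:
            raise GenepopParseError(
                f"line {line_no + 1}: {len(toks)} genotype fields, expected {n_loci}"
            )
        if current_pop_label is None:
            if pop_names is not None:
                current_pop_label = pop_names[pop_idx]
            else:
                current_pop_label = ident
        row = [_decode_genepop_call(t, line_no + 1) for t in toks]
        base_ident = ident
        k = 1
        while ident in individuals:
            k += 1
            ident = f"{base_ident}_{k}"
        individuals.append(ident)
        pops.append(current_pop_label)
        rows.append(row)
    if not rows:
        raise GenepopParseError("no genotype rows found")
    calls = np.array(rows, dtype=np.int32)
    try:
        return GenotypeTable(individuals, loci, calls, pops)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_genepop(table: GenotypeTable, path, title: str | None = None) -> None:
    """Write a canonical 3-digit Genepop file."""
    if table.n_individuals == 0 or table.n_loci == 0:
        raise ValidationError("cannot write an empty GenotypeTable")
    if (table.calls > 999).any():
        bad = int(table.calls.max())
        raise ValidationError(f"allele size {bad} exceeds 999 (3-digit Genepop encoding)")
    buf = _io.StringIO()
    buf.write((title or "hydropop genotypes") + "\n")
    for name in table.locus_names:
        buf.write(name + "\n")
    last_pop = object()
    for i, ind in enumerate(table.individuals):
        pop = table.populations[i]
        if pop != last_pop:
            buf.write("Pop\n")
            last_pop = pop
        alleles = []
        for j in range(table.n_loci):
            a1, a2 = table.calls[i, j]
            if a1 == MISSING:
                alleles.append("000000")
            else:
                alleles.append(f"{a1:03d}{a2:03d}")
        buf.write(f"{ind} ,  " + " ".join(alleles) + "\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta_alignment(path) -> SequenceAlignment:
    """Read an aligned FASTA file.

    A ``pop=LABEL`` token anywhere in a record's description assigns that
    sequence to a population.
    """
    records = {}
    population_of = {}
    for rec in SeqIO.parse(path, "fasta"):
        records[rec.id] = str(rec.seq)
        for tok in rec.description.split():
            if tok.startswith("pop="):
                population_of[rec.id] = tok[4:]
    if not records:
        raise ValidationError(f"{path}: empty or not FASTA")
    return SequenceAlignment(records, population_of)


def write_fasta_alignment(aln: SequenceAlignment, path) -> None:
    records = []
    for name, seq in aln.records.items():
        desc = f"pop={aln.population_of[name]}" if name in aln.population_of else ""
        records.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> GroupingScheme:
    """Read delimited population metadata.

    Expected columns: ``population``, ``group`` and either ``lat``/``lon``
    coordinates, an appended square distance block (columns named after the
    populations), or both.  An explicit distance matrix takes precedence over
    coordinate-derived great-circle distances.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "population" not in df.columns:
        raise ValidationError("metadata must have a 'population' column")
    pops = [str(p) for p in df["population"]]
    if len(set(pops)) != len(pops):
        dup = sorted({p for p in pops if pops.count(p) > 1})
        raise ValidationError(f"duplicate population labels in metadata: {dup}")
    group_of = {}
    if "group" in df.columns:
        group_of = {p: str(g) for p, g in zip(pops, df["group"])}
    coords = {}
    if "lat" in df.columns and "lon" in df.columns:
        coords = {
            p: (float(la), float(lo)) for p, la, lo in zip(pops, df["lat"], df["lon"])
        }
    distances = None
    if all(p.lower() in df.columns for p in pops):
        mat = df[[p.lower() for p in pops]].to_numpy(dtype=float)
        if not np.allclose(mat, mat.T):
            raise ValidationError("explicit distance block is not symmetric")
        distances = mat
    return GroupingScheme(
        populations=pops,
        group_of=group_of,
        coords=coords,
        distances=distances,
        distance_kind="hydrographic" if distances is not None else "euclidean",
    )


def write_metadata(scheme: GroupingScheme, path) -> None:
    import pandas as pd

    rows = []
    for p in scheme.populations:
        row = {"population": p, "group": scheme.group_of.get(p, "")}
        if p in scheme.coords:
            row["lat"], row["lon"] = scheme.coords[p]
        rows.append(row)
    df = pd.DataFrame(rows)
    if scheme.distances is not None:
        d = pd.DataFrame(
            np.asarray(scheme.distances, dtype=float),
            columns=[p.lower() for p in scheme.populations],
        )
        df = pd.concat([df.reset_index(drop=True), d], axis=1)
    df.to_csv(path, sep="\t", index=False)
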