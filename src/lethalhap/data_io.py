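"""Readers, writers and domain types shared by every pipeline stage.

All downstream modules consume only the types defined here: a marker map,
phased genotypes (two haplotype vectors per individual), a topologically
sorted pedigree, and plain :class:`pandas.DataFrame` tables for calving,
insemination and culling records.

Coordinates are 1-based inclusive base pairs.  Dates are ISO-8601.  Unknown
parents are coded with the sentinel ``"0"``.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lethalhap")

UNKNOWN_PARENT = "0"

MISSING = np.int8(-1)

#: stable column orders for :func:`write_results`
RESULT_COLUMNS = {
    "hhd": [
        "id", "chrom", "start", "end", "freq", "n_carriers", "obs_hom",
        "exp_random", "p_random", "exp_mating", "p_mating",
    ],
    "effects": ["haplotype", "beta", "se", "z", "p"],
    "gwas": ["marker", "chromosome", "position_bp", "allele_freq", "b", "se", "p_value"],
    "traits": ["animal", "trait", "value", "parity"],
}


class DataError(Exception):
    """Base class for all I/O and validation failures."""


class ParseError(DataError):
    """Malformed input file; the message names the offending line."""


class PhaseError(ParseError):
    """Genotype record is not phased."""


class PedigreeError(DataError):
    """Pedigree structure violation (cycle, missing column, ...)."""


# ---------------------------------------------------------------------------
# marker map and phased genotypes
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """SNP map on a linear assembly: id, chromosome, 1-based position, alleles."""

    table: pd.DataFrame  # columns: marker_id, chromosome, position_bp, ref, alt

    REQUIRED = ("marker_id", "chromosome", "position_bp", "ref", "alt")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataError(f"marker map missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        if self.table["marker_id"].duplicated().any():
            dup = self.table["marker_id"][self.table["marker_id"].duplicated()].iloc[0]
            raise DataError(f"duplicate marker id {dup!r}")
        for chrom, grp in self.table.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise DataError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chromosome"]))

    @property
    def positions(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    def chromosome_slice(self, chrom) -> slice:
        """Contiguous marker-index range of ``chrom`` (markers grouped by chromosome)."""
        idx = np.flatnonzero((self.table["chromosome"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.marker_ids == marker_id)
        if hits.size == 0:
            raise KeyError(marker_id)
        return int(hits[0])

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(indices)].reset_index(drop=True))


@dataclass
class PhasedGenotypes:
    """Phased allele calls: ``haplotypes[i, h, m]`` is allele *h* (0/1) of
    individual *i* at marker *m*; ``-1`` marks missing."""

    individuals: list
    haplotypes: np.ndarray  # int8, shape (n_individuals, 2, n_markers)
    marker_map: MarkerMap

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise DataError("haplotypes must have shape (n, 2, m)")
        if self.haplotypes.shape[0] != len(self.individuals):
            raise DataError("individual count does not match haplotype matrix")
        if self.haplotypes.shape[2] != self.marker_map.n_markers:
            raise DataError("marker count does not match haplotype matrix")
        bad = ~np.isin(self.haplotypes, (-1, 0, 1))
        if bad.any():
            raise DataError("allele codes must be 0, 1 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return self.marker_map.n_markers

    def dosages(self) -> np.ndarray:
        """Alt-allele counts per individual/marker as float; NaN where either
        haplotype is missing."""
        h = self.haplotypes.astype(float)
        h[h < 0] = np.nan
        return h.sum(axis=1)

    def subset_individuals(self, keep) -> "PhasedGenotypes":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        individuals = [self.individuals[i] for i in keep]
        return PhasedGenotypes(individuals, self.haplotypes[keep], self.marker_map)

    def subset_markers(self, indices) -> "PhasedGenotypes":
        indices = np.asarray(indices)
        return PhasedGenotypes(
            list(self.individuals),
            self.haplotypes[:, :, indices],
            self.marker_map.subset(indices),
        )


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Topologically sorted pedigree (parents precede offspring).

    ``table`` columns: individual, sire, dam, sex, birth_date, upg.  Unknown
    parents are the sentinel ``"0"``; ``upg`` (unknown-parent group) is set
    only on rows with at least one unknown parent, else ``""``.
    """

    table: pd.DataFrame
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for col in ("individual", "sire", "dam"):
            if col not in self.table.columns:
                raise PedigreeError(f"pedigree missing column {col!r}")
        for col, default in (("sex", ""), ("birth_date", ""), ("upg", "")):
            if col not in self.table.columns:
                self.table[col] = default
        self.table = _toposort_pedigree(self.table)
        self._index = {
            ind: i for i, ind in enumerate(self.table["individual"].to_numpy())
        }

    def __len__(self) -> int:
        return len(self.table)

    @property
    def individuals(self) -> np.ndarray:
        return self.table["individual"].to_numpy()

    def index_of(self, individual) -> int:
        return self._index[individual]

    def __contains__(self, individual) -> bool:
        return individual in self._index

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire_idx, dam_idx) arrays aligned with row order; -1 = unknown."""
        sire = np.array(
            [self._index.get(s, -1) for s in self.table["sire"]], dtype=np.int64
        )
        dam = np.array(
            [self._index.get(d, -1) for d in self.table["dam"]], dtype=np.int64
        )
        return sire, dam

    def sire_of(self, individual):
        s = self.table.at[self.index_of(individual), "sire"]
        return None if s == UNKNOWN_PARENT else s

    def dam_of(self, individual):
        d = self.table.at[self.index_of(individual), "dam"]
        return None if d == UNKNOWN_PARENT else d

    def maternal_grand_sire_of(self, individual):
        dam = self.dam_of(individual)
        if dam is None or dam not in self:
            return None
        return self.sire_of(dam)


def _toposort_pedigree(table: pd.DataFrame) -> pd.DataFrame:
    """Kahn's algorithm preserving input order among ready rows; raises
    :class:`PedigreeError` naming a cycle when one exists.  Parents referenced
    but absent from the table are inserted as founder rows (with a warning)."""
    table = table.copy()
    for col in ("individual", "sire", "dam"):
        table[col] = table[col].astype(str).replace({"nan": UNKNOWN_PARENT, "": UNKNOWN_PARENT})
    ids = set(table["individual"])
    if len(ids) != len(table):
        dup = table["individual"][table["individual"].duplicated()].iloc[0]
        raise PedigreeError(f"duplicate individual {dup!r}")
    referenced = (set(table["sire"]) | set(table["dam"])) - {UNKNOWN_PARENT}
    phantom = sorted(referenced - ids)
    if phantom:
        logger.warning("adding %d referenced-but-missing parents as founders", len(phantom))
        extra = pd.DataFrame(
            {
                "individual": phantom,
                "sire": UNKNOWN_PARENT,
                "dam": UNKNOWN_PARENT,
            }
        )
        for col in table.columns:
            if col not in extra.columns:
                extra[col] = ""
        table = pd.concat([extra[table.columns], table], ignore_index=True)

    idx = {ind: i for i, ind in enumerate(table["individual"])}
    n = len(table)
    indeg = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, (s, d) in enumerate(zip(table["sire"], table["dam"])):
        for p in (s, d):
            if p != UNKNOWN_PARENT:
                indeg[i] += 1
                children[idx[p]].append(i)
    queue = deque(i for i in range(n) if indeg[i] == 0)
    order = []
    while queue:
        i = queue.popleft()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) < n:
        cycle = _find_cycle(table, idx)
        raise PedigreeError(f"pedigree contains a cycle: {' -> '.join(cycle)}")
    out = table.iloc[order].reset_index(drop=True)
    return out


def _find_cycle(table: pd.DataFrame, idx: dict) -> list[str]:
    sires = table["sire"].to_numpy()
    dams = table["dam"].to_numpy()
    ids = table["individual"].to_numpy()

    state = {}
    stack: list[str] = []

    def visit(i: int):
        state[i] = 1
        stack.append(ids[i])
        for p in (sires[i], dams[i]):
            if p == UNKNOWN_PARENT:
                continue
            j = idx[p]
            if state.get(j) == 1:
                k = stack.index(ids[j])
                return stack[k:] + [ids[j]]
            if state.get(j) is None:
                found = visit(j)
                if found:
                    return found
        state[i] = 2
        stack.pop()
        return None

    for i in range(len(table)):
        if state.get(i) is None:
            found = visit(i)
            if found:
                return found
    return []


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_phased_genotypes(path, format_name: str, map_path=None) -> PhasedGenotypes:
    """Read phased genotypes from ``phased-vcf`` or ``hapmatrix-tsv``.

    The hapmatrix dialect is one header line of marker ids followed by two
    rows per individual (ids suffixed ``_A`` / ``_B``); its marker map lives
    in a companion ``<stem>.map.tsv`` unless ``map_path`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if format_name == "phased-vcf":
        return _read_phased_vcf(path)
    if format_name == "hapmatrix-tsv":
        return _read_hapmatrix(path, map_path)
    raise DataError(f"unknown genotype format {format_name!r}")


def _read_phased_vcf(path: Path) -> PhasedGenotypes:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed headers
        raise ParseError(f"{path}: cannot open as VCF ({exc})") from exc
    individuals = list(vcf.samples)
    rows = []
    records = []
    for lineno, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise ParseError(
                f"{path}: record {lineno} ({var.CHROM}:{var.POS}) is not biallelic"
            )
        gts = var.genotypes  # [a0, a1, phased] per sample
        alleles = np.full((len(individuals), 2), MISSING, dtype=np.int8)
        for i, gt in enumerate(gts):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 >= 0 and a1 >= 0 and not phased:
                raise PhaseError(
                    f"{path}: unphased genotype for sample {individuals[i]!r} "
                    f"at record {lineno} ({var.CHROM}:{var.POS})"
                )
            alleles[i, 0] = a0 if a0 >= 0 else MISSING
            alleles[i, 1] = a1 if a1 >= 0 else MISSING
        rows.append(alleles)
        chrom = int(var.CHROM) if str(var.CHROM).isdigit() else var.CHROM
        records.append(
            (var.ID or f"{var.CHROM}:{var.POS}", chrom, var.POS, var.REF, var.ALT[0])
        )
    if not records:
        raise ParseError(f"{path}: no variant records")
    marker_map = MarkerMap(
        pd.DataFrame(records, columns=["marker_id", "chromosome", "position_bp", "ref", "alt"])
    )
    haplotypes = np.stack(rows, axis=2)  # (n, 2, m)
    return PhasedGenotypes(individuals, haplotypes, marker_map)


def _read_hapmatrix(path: Path, map_path=None) -> PhasedGenotypes:
    if map_path is None:
        map_path = path.with_suffix("").with_suffix("")  # strip e.g. .haps.tsv
        map_path = Path(str(path).rsplit(".haps", 1)[0] + ".map.tsv")
    map_path = Path(map_path)
    if not map_path.exists():
        raise DataError(f"hapmatrix map file not found: {map_path}")
    mm = MarkerMap(pd.read_csv(map_path, sep="\t", dtype={"marker_id": str, "ref": str, "alt": str}))

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "individual":
            raise ParseError(f"{path}: line 1: header must start with 'individual'")
        marker_ids = header[1:]
        if marker_ids != list(mm.marker_ids):
            raise ParseError(f"{path}: header marker ids do not match {map_path}")
        individuals: list[str] = []
        hapA, hapB = [], []
        pending: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(marker_ids) + 1:
                raise ParseError(f"{path}: line {lineno}: expected {len(marker_ids)+1} fields")
            label = fields[0]
            if not (label.endswith("_A") or label.endswith("_B")):
                raise ParseError(f"{path}: line {lineno}: row label must end in _A or _B")
            ind, suffix = label[:-2], label[-1]
            try:
                row = np.array(
                    [MISSING if v == "." else np.int8(v) for v in fields[1:]], dtype=np.int8
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad allele code ({exc})") from exc
            if suffix == "A":
                if ind in pending:
                    raise ParseError(f"{path}: line {lineno}: duplicate _A row for {ind!r}")
                pending[ind] = row
            else:
                if ind not in pending:
                    raise ParseError(f"{path}: line {lineno}: _B row for {ind!r} without _A")
                individuals.append(ind)
                hapA.append(pending.pop(ind))
                hapB.append(row)
    if pending:
        raise ParseError(f"{path}: missing _B row for {sorted(pending)[0]!r}")
    haplotypes = np.stack([np.stack(hapA), np.stack(hapB)], axis=1)
    return PhasedGenotypes(individuals, haplotypes, mm)


def read_pedigree(path) -> Pedigree:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"individual", "sire", "dam"}
    if not required.issubset(table.columns):
        raise ParseError(f"{path}: header must include {sorted(required)}")
    return Pedigree(table)


def _read_record_table(path, required: set, date_cols=("date",)) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    table = pd.read_csv(path, dtype={c: str for c in ("dam", "sire", "calf", "cow", "technician", "herd")})
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in date_cols:
        table[col] = pd.to_datetime(table[col], format="ISO8601")
    return table


def read_calvings(path) -> pd.DataFrame:
    """Calving records: dam, sire, calf, date, parity, calf_sex, outcome, twin."""
    table = _read_record_table(
        path, {"dam", "sire", "calf", "date", "parity", "calf_sex", "outcome", "twin"}
    )
    table["parity"] = table["parity"].astype(int)
    if (table["parity"] < 0).any():
        raise DataError("negative parity in calving records")
    table["twin"] = table["twin"].astype(int).astype(bool)
    return table


def read_inseminations(path) -> pd.DataFrame:
    """Insemination records: cow, date, technician, lactation."""
    table = _read_record_table(path, {"cow", "date", "technician", "lactation"})
    table["lactation"] = table["lactation"].astype(int)
    return table


def read_cullings(path) -> pd.DataFrame:
    """Culling records: cow, date, reason."""
    return _read_record_table(path, {"cow", "date", "reason"})


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path, kind: str) -> None:
    """Write a results table as TSV with a stable, documented column order.

    Floats are written with 8 significant digits, which round-trips through
    :func:`read_results` at that precision.
    """
    if kind not in RESULT_COLUMNS:
        raise DataError(f"unknown result kind {kind!r}")
    lead = [c for c in RESULT_COLUMNS[kind] if c in table.columns]
    rest = [c for c in table.columns if c not in lead]
    ordered = table[lead + rest]
    path = Path(path)
    try:
        ordered.to_csv(path, sep="\t", index=False, float_format="%.8g")
    except OSError as exc:
        raise DataError(f"cannot write {path}: {exc}") from exc


def read_results(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t")


def write_phased_vcf(phased: PhasedGenotypes, path) -> None:
    """Minimal uncompressed phased VCF (GT only, '|' separator)."""
    mm = phased.marker_map.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, grp in mm.groupby("chromosome", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['position_bp'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in phased.individuals)
            + "\n"
        )
        haps = phased.haplotypes
        for m in range(phased.n_markers):
            row = mm.iloc[m]
            gts = []
            for i in range(phased.n_individuals):
                a0, a1 = haps[i, 0, m], haps[i, 1, m]
                gts.append(
                    f"{'.' if a0 < 0 else int(a0)}|{'.' if a1 < 0 else int(a1)}"
                )
            fh.write(
                f"{row['chromosome']}\t{int(row['position_bp'])}\t{row['marker_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_hapmatrix(phased: PhasedGenotypes, path, map_path=None) -> None:
    """Write the two-row-per-individual haplotype matrix plus companion map."""
    path = Path(path)
    if map_path is None:
        map_path = Path(str(path).rsplit(".haps", 1)[0] + ".map.tsv")
    phased.marker_map.table.to_csv(map_path, sep="\t", index=False)
    haps = phased.haplotypes
    with open(path, "w") as fh:
        fh.write("individual\t" + "\t".join(map(str, phased.marker_map.marker_ids)) + "\n")
        for i, ind in enumerate(phased.individuals):
            for h, suffix in ((0, "A"), (1, "B")):
                vals = "\t".join(
                    "." if a < 0 else str(int(a)) for a in haps[i, h]
                )
                fh.write(f"{ind}_{suffix}\t{vals}\n")


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration and logging
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such config file: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise DataError(f"{path}: config must be a YAML mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
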