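"""Genotype containers and file I/O for codominant multi-allelic markers.

The pipeline's backbone is :class:`GenotypeDataset`: diploid allele calls for
individuals at microsatellite-style loci, tied to a locality metadata table
(species, region, sympatry status, coordinates).  Raw fragment lengths are
binned into discrete alleles whose identifiers are integer representative
sizes (bin midpoints), so that allele-size statistics such as Rst remain
meaningful downstream.

Supported formats: GENEPOP (via Biopython's parser, 2- or 3-digit codes),
STRUCTURE-style two-row tables, and CSV metadata / maternal-label tables.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.PopGen.GenePop import read as _genepop_read

logger = logging.getLogger(__name__)

#: Internal sentinel for a missing allele call (distinct from any allele id).
MISSING = -1

META_COLUMNS = [
    "locality",
    "species",
    "region",
    "sympatry",
    "lat",
    "lon",
    "coord_system",
    "group",
]


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype files or inconsistent configuration."""


@dataclass(frozen=True)
class LocusDef:
    """Definition of one locus: name, optional fragment-length bin edges.

    ``bin_edges`` are ordered breakpoints in base pairs; ``k+1`` edges define
    ``k`` left-closed right-open bins.  The allele identifier for a bin is its
    midpoint rounded to the nearest integer, which doubles as the allele's
    representative fragment size.  Loci created from already-discrete calls
    (e.g. read from GENEPOP) carry ``bin_edges=None``.
    """

    name: str
    bin_edges: tuple[float, ...] | None = None
    missing_code: int = 0

    def __post_init__(self):
        if self.bin_edges is not None:
            edges = tuple(float(e) for e in self.bin_edges)
            if len(edges) < 2:
                raise GenotypeFormatError(
                    f"locus {self.name!r}: need at least 2 bin edges (1 bin)"
                )
            if not np.all(np.diff(edges) > 0):
                raise GenotypeFormatError(
                    f"locus {self.name!r}: bin edges must be strictly increasing"
                )
            object.__setattr__(self, "bin_edges", edges)

    @property
    def allele_ids(self) -> np.ndarray:
        """Representative allele sizes: rounded bin midpoints."""
        if self.bin_edges is None:
            raise GenotypeFormatError(f"locus {self.name!r} has no bin edges")
        e = np.asarray(self.bin_edges)
        return np.round((e[:-1] + e[1:]) / 2.0).astype(int)

    def assign(self, lengths: np.ndarray) -> np.ndarray:
        """Assign raw fragment lengths to allele ids (MISSING if out of range).

        Intervals are left-closed, right-open: a length equal to an interior
        edge belongs to the bin on its right.
        """
        if self.bin_edges is None:
            raise GenotypeFormatError(f"locus {self.name!r} has no bin edges")
        x = np.asarray(lengths, dtype=float)
        edges = np.asarray(self.bin_edges)
        idx = np.searchsorted(edges, x, side="right") - 1
        ok = (idx >= 0) & (idx < len(edges) - 1) & np.isfinite(x)
        ids = self.allele_ids
        out = np.where(ok, ids[np.clip(idx, 0, len(ids) - 1)], MISSING)
        return out.astype(int)


@dataclass
class GenotypeDataset:
    """Individuals x loci diploid allele calls plus locality metadata.

    Attributes
    ----------
    individual_ids : list of str
    localities : list of str, one per individual
    loci : list of LocusDef
    calls : int array, shape (n_individuals, n_loci, 2); MISSING for no call
    meta : optional DataFrame with columns META_COLUMNS, one row per locality
    maternal : optional array of per-individual maternal species labels
        ("A", "B", or "unknown"), standing in for mitochondrial assignment.
    """

    individual_ids: list[str]
    localities: list[str]
    loci: list[LocusDef]
    calls: np.ndarray
    meta: pd.DataFrame | None = None
    maternal: np.ndarray | None = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=int)
        n, L = len(self.individual_ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise GenotypeFormatError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(self.localities) != n:
            raise GenotypeFormatError("one locality per individual required")
        if self.meta is not None:
            missing = set(self.localities) - set(self.meta["locality"])
            if missing:
                raise GenotypeFormatError(
                    f"localities absent from metadata: {sorted(missing)}"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def subset(self, indices) -> "GenotypeDataset":
        """Dataset restricted to the given individual indices (order kept)."""
        idx = np.asarray(indices, dtype=int)
        return GenotypeDataset(
            individual_ids=[self.individual_ids[i] for i in idx],
            localities=[self.localities[i] for i in idx],
            loci=self.loci,
            calls=self.calls[idx],
            meta=self.meta,
            maternal=None if self.maternal is None else self.maternal[idx],
        )

    def indices_for_localities(self, localities) -> np.ndarray:
        wanted = set(localities)
        return np.array(
            [i for i, loc in enumerate(self.localities) if loc in wanted],
            dtype=int,
        )

    def locality_of_individual(self) -> pd.Series:
        return pd.Series(self.localities, index=self.individual_ids)

    def allele_universe(self, locus_index: int) -> np.ndarray:
        """Sorted distinct non-missing allele ids observed at a locus."""
        a = self.calls[:, locus_index, :].ravel()
        return np.unique(a[a != MISSING])

    def drop_loci(self, names) -> "GenotypeDataset":
        """Locus-exclusion filter (e.g. markers with high null-allele rates)."""
        drop = set(names)
        keep = [i for i, l in enumerate(self.loci) if l.name not in drop]
        if len(keep) == len(self.loci):
            logger.warning("drop_loci: no matching loci among %s", sorted(drop))
        return GenotypeDataset(
            individual_ids=self.individual_ids,
            localities=self.localities,
            loci=[self.loci[i] for i in keep],
            calls=self.calls[:, keep, :],
            meta=self.meta,
            maternal=self.maternal,
        )


@dataclass
class ReferencePair:
    """Indices of pooled parental reference individuals within a dataset."""

    dataset: GenotypeDataset
    idx_a: np.ndarray
    idx_b: np.ndarray

    def __post_init__(self):
        self.idx_a = np.asarray(self.idx_a, dtype=int)
        self.idx_b = np.asarray(self.idx_b, dtype=int)
        if self.idx_a.size == 0:
            raise ValueError("reference pool for species A is empty")
        if self.idx_b.size == 0:
            raise ValueError("reference pool for species B is empty")
        if set(self.idx_a) & set(self.idx_b):
            raise ValueError("reference pools must be disjoint")

    @property
    def n_a(self) -> int:
        return self.idx_a.size

    @property
    def n_b(self) -> int:
        return self.idx_b.size


# ---------------------------------------------------------------------------
# fragment binning
# ---------------------------------------------------------------------------

def bin_fragments(
    raw_lengths: np.ndarray,
    loci: list[LocusDef],
    individual_ids: list[str],
    localities: list[str],
    meta: pd.DataFrame | None = None,
) -> GenotypeDataset:
    """Bin raw fragment lengths (n, L, 2) into discrete allele calls.

    Each length is assigned to the left-closed right-open bin containing it;
    lengths falling outside all bins (or NaN) become missing, with a logged
    warning giving the count per locus.
    """
    raw = np.asarray(raw_lengths, dtype=float)
    n, L = len(individual_ids), len(loci)
    if raw.shape != (n, L, 2):
        raise GenotypeFormatError(f"raw_lengths shape {raw.shape} != ({n},{L},2)")
    calls = np.empty((n, L, 2), dtype=int)
    for j, locus in enumerate(loci):
        assigned = locus.assign(raw[:, j, :])
        n_out = int(np.sum((assigned == MISSING) & np.isfinite(raw[:, j, :])))
        if n_out:
            logger.warning(
                "locus %s: %d fragment lengths outside all bins -> missing",
                locus.name,
                n_out,
            )
        calls[:, j, :] = assigned
    return GenotypeDataset(individual_ids, list(localities), list(loci), calls, meta)


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

_GENO_TOKEN = re.compile(r"^\d+$")


def _validate_genepop_widths(text: str) -> None:
    """Check genotype token widths are uniform per locus column (4 or 6)."""
    lines = text.splitlines()
    widths: dict[int, int] = {}
    in_pops = False
    for lineno, line in enumerate(lines, start=1):
        if line.strip().lower() == "pop":
            in_pops = True
            continue
        if not in_pops or "," not in line:
            continue
        _, _, geno = line.partition(",")
        for j, tok in enumerate(geno.split()):
            if not _GENO_TOKEN.match(tok):
                raise GenotypeFormatError(
                    f"line {lineno}: non-numeric genotype token {tok!r}"
                )
            if len(tok) not in (4, 6):
                raise GenotypeFormatError(
                    f"line {lineno}: genotype token {tok!r} is not a 2- or "
                    f"3-digit diploid code"
                )
            prev = widths.setdefault(j, len(tok))
            if prev != len(tok):
                raise GenotypeFormatError(
                    f"line {lineno}: mixed allele-code widths at locus column "
                    f"{j + 1} ({prev} vs {len(tok)} characters)"
                )


def read_genepop(path, meta: pd.DataFrame | None = None) -> GenotypeDataset:
    """Read a GENEPOP file into a GenotypeDataset.

    Populations become localities.  If individual names contain a colon they
    are split as ``locality:individual`` (the convention :func:`write_genepop`
    uses); otherwise populations are named ``pop1..popK``.  Zero allele codes
    ("00"/"000") are parsed as missing.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    _validate_genepop_widths(text)
    rec = _genepop_read(io.StringIO(text))
    loci = [LocusDef(name) for name in rec.loci_list]
    ids, locs, rows = [], [], []
    for p, pop in enumerate(rec.populations, start=1):
        for name, genotype in pop:
            name = name.strip()
            if ":" in name:
                loc, _, ind = name.partition(":")
            else:
                loc, ind = f"pop{p}", name
            ids.append(ind)
            locs.append(loc)
            rows.append(
                [
                    (
                        MISSING if a is None or a == 0 else int(a),
                        MISSING if b is None or b == 0 else int(b),
                    )
                    for a, b in genotype
                ]
            )
    calls = np.array(rows, dtype=int) if rows else np.empty((0, len(loci), 2), int)
    return GenotypeDataset(ids, locs, loci, calls, meta)


def write_genepop(dataset: GenotypeDataset, path, title: str = "hybzone export") -> None:
    """Write a GENEPOP file (3-digit codes, deterministic ordering).

    Individuals are written grouped by locality (sorted), then by individual
    id, with names encoded ``locality:individual`` so a round trip preserves
    locality assignment.  Missing calls become ``000000``.
    """
    for j in range(dataset.n_loci):
        uni = dataset.allele_universe(j)
        if uni.size and (uni.max() > 999 or uni.min() < 1):
            raise GenotypeFormatError(
                f"locus {dataset.loci[j].name!r}: allele ids must be in 1..999 "
                f"for 3-digit GENEPOP encoding"
            )
    order = sorted(
        range(dataset.n_individuals),
        key=lambda i: (dataset.localities[i], dataset.individual_ids[i]),
    )
    lines = [title]
    lines.extend(dataset.locus_names)
    current_loc = None
    for i in order:
        loc = dataset.localities[i]
        if loc != current_loc:
            lines.append("Pop")
            current_loc = loc
        geno = " ".join(
            "".join(
                f"{a:03d}" if a != MISSING else "000"
                for a in dataset.calls[i, j]
            )
            for j in range(dataset.n_loci)
        )
        lines.append(f"{loc}:{dataset.individual_ids[i]} , {geno}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# STRUCTURE two-row format
# ---------------------------------------------------------------------------

def read_structure(path, meta: pd.DataFrame | None = None) -> GenotypeDataset:
    """Read a two-row STRUCTURE table (tab-separated, -9 = missing).

    Expected layout: a header row ``individual<TAB>locality<TAB><locus...>``
    then two consecutive rows per individual, one per allele copy.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    locus_names = list(df.columns[2:])
    if len(df) % 2 != 0:
        raise GenotypeFormatError("two-row STRUCTURE file has an odd row count")
    ids, locs, rows = [], [], []
    for k in range(0, len(df), 2):
        r1, r2 = df.iloc[k], df.iloc[k + 1]
        if r1.iloc[0] != r2.iloc[0]:
            raise GenotypeFormatError(
                f"rows {k + 2}/{k + 3}: allele-copy rows belong to different "
                f"individuals ({r1.iloc[0]!r} vs {r2.iloc[0]!r})"
            )
        ids.append(str(r1.iloc[0]))
        locs.append(str(r1.iloc[1]))
        a1 = r1.iloc[2:].astype(int).to_numpy()
        a2 = r2.iloc[2:].astype(int).to_numpy()
        geno = np.stack([a1, a2], axis=1)
        geno[geno == -9] = MISSING
        rows.append(geno)
    loci = [LocusDef(n) for n in locus_names]
    calls = np.array(rows, int) if rows else np.empty((0, len(loci), 2), int)
    return GenotypeDataset(ids, locs, loci, calls, meta)


def write_structure(dataset: GenotypeDataset, path) -> None:
    """Write the two-row STRUCTURE table read by :func:`read_structure`."""
    cols = ["individual", "locality"] + dataset.locus_names
    rows = []
    order = sorted(
        range(dataset.n_individuals),
        key=lambda i: (dataset.localities[i], dataset.individual_ids[i]),
    )
    for i in order:
        for copy in (0, 1):
            alleles = [
                -9 if a == MISSING else int(a) for a in dataset.calls[i, :, copy]
            ]
            rows.append(
                [dataset.individual_ids[i], dataset.localities[i]] + alleles
            )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# metadata and maternal labels
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read a locality metadata CSV and validate its columns and values."""
    meta = pd.read_csv(path, dtype={"locality": str, "region": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    for col in ("locality", "species", "sympatry"):
        if col not in meta.columns:
            raise GenotypeFormatError(f"metadata missing required column {col!r}")
    for col in META_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    bad = set(meta["sympatry"].dropna()) - {"sympatric", "allopatric"}
    if bad:
        raise GenotypeFormatError(f"invalid sympatry values: {sorted(bad)}")
    if meta["locality"].duplicated().any():
        raise GenotypeFormatError("duplicate locality ids in metadata")
    coords = meta[["lat", "lon"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords) | np.isnan(coords)):
        raise GenotypeFormatError("coordinates must be finite")
    return meta


def read_maternal_labels(path) -> pd.Series:
    """Read a CSV with columns (individual, maternal) into a Series."""
    df = pd.read_csv(path, dtype=str)
    bad = set(df["maternal"]) - {"A", "B", "unknown"}
    if bad:
        raise GenotypeFormatError(f"invalid maternal labels: {sorted(bad)}")
    return df.set_index("individual")["maternal"]


def attach_maternal(dataset: GenotypeDataset, labels: pd.Series) -> GenotypeDataset:
    arr = np.array(
        [labels.get(i, "unknown") for i in dataset.individual_ids], dtype=object
    )
    return replace(dataset, maternal=arr)


# ---------------------------------------------------------------------------
# reference pooling
# ---------------------------------------------------------------------------

def _match_localities(meta: pd.DataFrame, selector) -> list[str]:
    """Localities matching a selector: a dict of column=value constraints,
    an explicit list of locality ids, or a callable on metadata rows."""
    if callable(selector):
        mask = meta.apply(selector, axis=1).astype(bool)
        return list(meta.loc[mask, "locality"])
    if isinstance(selector, (list, tuple, set)):
        return [l for l in meta["locality"] if l in set(selector)]
    mask = pd.Series(True, index=meta.index)
    for col, val in selector.items():
        mask &= meta[col] == val
    return list(meta.loc[mask, "locality"])


def parse_selector(text: str) -> dict:
    """Parse ``"species=A,sympatry=allopatric"`` into a selector dict."""
    out = {}
    for part in text.split(","):
        key, _, val = part.partition("=")
        if not _ or not key.strip():
            raise GenotypeFormatError(f"bad selector fragment {part!r}")
        out[key.strip()] = val.strip()
    return out


def pool_references(
    dataset: GenotypeDataset,
    selector_a,
    selector_b,
    overrides_a=(),
    overrides_b=(),
) -> ReferencePair:
    """Pool allopatric localities into two parental reference groups.

    ``selector_a``/``selector_b`` choose localities via the metadata table
    (dict of equality constraints, explicit list, or callable).  ``overrides``
    add explicitly-named localities (e.g. tiny single-individual samples
    merged into a neighbouring county's group).
    """
    if dataset.meta is None:
        raise GenotypeFormatError("pool_references requires locality metadata")
    locs_a = set(_match_localities(dataset.meta, selector_a)) | set(overrides_a)
    locs_b = set(_match_localities(dataset.meta, selector_b)) | set(overrides_b)
    idx_a = dataset.indices_for_localities(locs_a)
    idx_b = dataset.indices_for_localities(locs_b)
    if idx_a.size == 0:
        raise ValueError("no individuals matched for reference species A")
    if idx_b.size == 0:
        raise ValueError("no individuals matched for reference species B")
    return ReferencePair(dataset, idx_a, idx_b)
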