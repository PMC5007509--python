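"""Core data types and file formats for autosomal STR analysis.

STR alleles are named by repeat count, with microvariants carrying a
partial-repeat suffix ("9.3" is nine full repeats plus three bases).
Genotype tables hold unordered diploid calls per individual and locus;
allele-frequency tables are the unit on which every frequency-based
statistic operates.  Distance matrices are :class:`skbio.DistanceMatrix`
objects and trees are :class:`skbio.TreeNode` objects, so the whole
scikit-bio toolbox applies to them directly.
"""

from __future__ import annotations

import csv
import functools
import io
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "AlleleLabel",
    "GenotypeTable",
    "AlleleFrequencyTable",
    "LocusSummary",
    "PopulationSet",
    "read_genotypes",
    "write_genotypes",
    "read_frequency_table",
    "write_frequency_table",
    "count_alleles",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_newick",
    "write_newick",
    "read_population_set",
    "write_population_set",
    "load_gorkha_frequencies",
    "load_nei_da_matrix",
    "GORKHA_LOCI",
]

#: The 15 autosomal loci of the Identifiler panel, in published table order.
GORKHA_LOCI = (
    "D8S1179", "D21S11", "D7S820", "CSF1PO", "D3S1358", "TH01", "D13S317",
    "D16S539", "D2S1338", "D19S433", "vWA", "TPOX", "D18S51", "D5S818", "FGA",
)

_SUMMARY_LABELS = {
    "pd": "pd", "pic": "pic", "pe": "pe", "pi": "pi",
    "hobs": "h_obs", "h_obs": "h_obs", "hexp": "h_exp", "h_exp": "h_exp",
    "p value": "hwe_p", "p_value": "hwe_p", "pvalue": "hwe_p", "pm": "pm",
}


@functools.total_ordering
@dataclass(frozen=True)
class AlleleLabel:
    """An STR allele: full repeat units plus a 0-3 base partial repeat.

    Stored as an integer pair rather than a float so that microvariant
    labels are exact ("9.3" can never collide with a rounded 9.30) and
    "10" and "10.0" normalize to the same allele.
    """

    repeats: int
    partial: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError(f"repeat count must be >= 1, got {self.repeats}")
        if self.partial not in (0, 1, 2, 3):
            raise ValueError(f"partial repeat must be in 0..3, got {self.partial}")

    @classmethod
    def parse(cls, token: str | int | float | "AlleleLabel") -> "AlleleLabel":
        if isinstance(token, AlleleLabel):
            return token
        if isinstance(token, int):
            return cls(token)
        text = str(token).strip()
        try:
            if "." in text:
                whole, frac = text.split(".")
                return cls(int(whole), int(frac))
            return cls(int(text))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparseable allele token {token!r}") from exc

    def __str__(self) -> str:
        return f"{self.repeats}.{self.partial}" if self.partial else str(self.repeats)

    @property
    def value(self) -> float:
        """Numeric sort key: repeats + partial/10."""
        return self.repeats + self.partial / 10.0

    def __lt__(self, other: "AlleleLabel") -> bool:
        return (self.repeats, self.partial) < (other.repeats, other.partial)


Call = tuple[AlleleLabel, AlleleLabel]


@dataclass
class GenotypeTable:
    """Unordered diploid STR calls for a sample of individuals.

    ``calls[(sample, locus)]`` is either ``None`` (missing) or a pair of
    :class:`AlleleLabel`, canonicalized ascending; homozygotes repeat the
    same label twice.
    """

    sample_ids: list[str]
    loci: list[str]
    calls: dict[tuple[str, str], Call | None]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            raise ValueError(f"duplicate sample id(s): {sorted(dupes)}")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names")
        for key, call in self.calls.items():
            if call is not None and len(call) != 2:
                raise ValueError(f"call at {key} is not a diploid pair")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def genotypes_at(self, locus: str) -> list[Call]:
        """Non-missing calls at *locus*, in sample order."""
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        out = []
        for s in self.sample_ids:
            call = self.calls.get((s, locus))
            if call is not None:
                out.append(call)
        return out

    def n_typed(self, locus: str) -> int:
        return len(self.genotypes_at(locus))


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies with the sample size behind them.

    ``n`` is the number of typed individuals per locus (2n gene copies).
    ``published`` optionally carries per-locus summary statistics read
    alongside a frequency file (e.g. the PD/PIC/PE/PI/Hobs/Hexp/p/Pm rows
    of a published table), keyed by statistic then locus.
    """

    loci: list[str]
    n: dict[str, int]
    freqs: dict[str, dict[AlleleLabel, float]]
    published: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, tol: float = 0.01) -> None:
        for locus in self.loci:
            fr = self.freqs[locus]
            if any(f <= 0 for f in fr.values()):
                raise ValueError(f"non-positive frequency at locus {locus}")
            total = sum(fr.values())
            if not (1 - tol <= total <= 1 + tol):
                raise ValueError(
                    f"frequencies at locus {locus} sum to {total:.4f}, "
                    f"outside [{1 - tol}, {1 + tol}]"
                )

    @classmethod
    def from_genotypes(cls, g: GenotypeTable) -> "AlleleFrequencyTable":
        from .forensic_stats import allele_frequencies  # cycle-free at call time

        n: dict[str, int] = {}
        freqs: dict[str, dict[AlleleLabel, float]] = {}
        for locus in g.loci:
            fr, n_loc = allele_frequencies(g, locus)
            freqs[locus], n[locus] = fr, n_loc
        return cls(list(g.loci), n, freqs)

    def counts(self, locus: str) -> dict[AlleleLabel, int]:
        """Allele copy counts reconstructed as round(freq * 2n)."""
        two_n = 2 * self.n[locus]
        return {a: int(round(f * two_n)) for a, f in self.freqs[locus].items()}


@dataclass
class LocusSummary:
    """One locus's row of a forensic summary table."""

    locus: str
    h_obs: float
    h_exp: float
    pic: float
    pm: float
    pd: float
    pe: float
    pi: float
    hwe_p: float | None = None

    def __post_init__(self) -> None:
        for name in ("h_obs", "h_exp", "pic", "pm", "pd", "pe"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1] at locus {self.locus}")
        if self.pi <= 0:
            raise ValueError(f"pi must be positive at locus {self.locus}")
        if abs((1.0 - self.pm) - self.pd) > 1e-9:
            raise ValueError(f"pd != 1 - pm at locus {self.locus}")
        if self.hwe_p is not None and not (0.0 < self.hwe_p <= 1.0):
            raise ValueError(f"hwe_p={self.hwe_p} outside (0, 1]")


@dataclass
class PopulationSet:
    """Named populations sharing a locus panel, each an AlleleFrequencyTable.

    Allele domains are unioned per locus on demand; an allele absent from a
    population contributes frequency 0 there.
    """

    populations: dict[str, AlleleFrequencyTable]

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("empty population set")
        loci_sets = {name: tuple(t.loci) for name, t in self.populations.items()}
        ref = next(iter(loci_sets.values()))
        for name, loci in loci_sets.items():
            if set(loci) != set(ref):
                raise ValueError(f"population {name!r} covers different loci")

    @property
    def names(self) -> list[str]:
        return list(self.populations)

    @property
    def loci(self) -> list[str]:
        return list(next(iter(self.populations.values())).loci)

    def frequency_matrix(self, locus: str, names: Sequence[str] | None = None
                         ) -> tuple[list[AlleleLabel], np.ndarray]:
        """Union allele domain and the (populations x alleles) frequency matrix."""
        names = list(names) if names is not None else self.names
        domain = sorted({a for nm in names for a in self.populations[nm].freqs[locus]})
        mat = np.zeros((len(names), len(domain)))
        index = {a: j for j, a in enumerate(domain)}
        for i, nm in enumerate(names):
            for a, f in self.populations[nm].freqs[locus].items():
                mat[i, index[a]] = f
        return domain, mat

    def subset_loci(self, loci: Sequence[str]) -> "PopulationSet":
        """Restrict (with multiplicity) to *loci* — the bootstrap resampling unit.

        Repeated locus names get suffixed copies so a bootstrap draw with
        replacement yields a valid table.
        """
        pops = {}
        for name, table in self.populations.items():
            new_loci, n, freqs = [], {}, {}
            seen: dict[str, int] = {}
            for locus in loci:
                k = seen.get(locus, 0)
                seen[locus] = k + 1
                alias = locus if k == 0 else f"{locus}#{k}"
                new_loci.append(alias)
                n[alias] = table.n[locus]
                freqs[alias] = dict(table.freqs[locus])
            pops[name] = AlleleFrequencyTable(new_loci, n, freqs,
                                              published=None)
        return PopulationSet(pops)


# ---------------------------------------------------------------------------
# Genotype CSV

def _parse_cell(cell: str, sample: str, locus: str) -> Call | None:
    text = cell.strip()
    if not text:
        return None
    parts = text.split("/")
    try:
        if len(parts) == 1:
            a = AlleleLabel.parse(parts[0])
            return (a, a)
        if len(parts) == 2:
            a, b = AlleleLabel.parse(parts[0]), AlleleLabel.parse(parts[1])
            return (a, b) if a <= b else (b, a)
    except ValueError:
        pass
    raise ValueError(f"unparseable allele token {cell!r} at sample {sample!r}, "
                     f"locus {locus!r}")


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read the canonical genotype CSV: ``sample,<locus1>,<locus2>,...``

    Cells are ``a/b``, ``a`` (homozygote shorthand) or empty (missing).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0].lower() != "sample":
        raise ValueError("first column of a genotype CSV must be 'sample'")
    loci = list(df.columns[1:])
    sample_ids = list(df.iloc[:, 0])
    seen = set()
    for s in sample_ids:
        if s in seen:
            raise ValueError(f"duplicate sample id: {s!r}")
        seen.add(s)
    calls: dict[tuple[str, str], Call | None] = {}
    for _, row in df.iterrows():
        s = row.iloc[0]
        for locus in loci:
            calls[(s, locus)] = _parse_cell(row[locus], s, locus)
    return GenotypeTable(sample_ids, loci, calls)


def write_genotypes(g: GenotypeTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", *g.loci])
        for s in g.sample_ids:
            row = [s]
            for locus in g.loci:
                call = g.calls.get((s, locus))
                row.append("" if call is None else f"{call[0]}/{call[1]}")
            w.writerow(row)


# ---------------------------------------------------------------------------
# Frequency tables (published-table layout)

def read_frequency_table(path: str | Path, default_n: int | None = None,
                         tol: float = 0.01) -> AlleleFrequencyTable:
    """Read a frequency CSV in published-table layout.

    First column ``Allele``, one column per locus, blank cells meaning the
    allele is absent.  Rows whose label is a summary statistic (PD, PIC, PE,
    PI, Hobs, Hexp, p_value, Pm) are split off into ``table.published``; a
    row labelled ``n`` gives per-locus sample sizes (else *default_n* must
    be supplied).  A locus whose frequencies sum outside ``1 +/- tol`` is an
    error naming the locus.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    loci = list(df.columns[1:])
    freqs: dict[str, dict[AlleleLabel, float]] = {locus: {} for locus in loci}
    published: dict[str, dict[str, float]] = {}
    n: dict[str, int] = {}
    for _, row in df.iterrows():
        label = str(row.iloc[0]).strip()
        key = _SUMMARY_LABELS.get(label.lower().replace(" ", "_").replace("__", "_"))
        if key is None:
            key = _SUMMARY_LABELS.get(label.lower())
        if label.lower() == "n":
            for locus in loci:
                if str(row[locus]).strip():
                    n[locus] = int(float(row[locus]))
            continue
        if key is not None:
            published[key] = {locus: float(row[locus]) for locus in loci
                              if str(row[locus]).strip()}
            continue
        allele = AlleleLabel.parse(label)
        for locus in loci:
            cell = str(row[locus]).strip()
            if cell:
                freqs[locus][allele] = float(cell)
    if not n:
        if default_n is None:
            raise ValueError("no 'n' row in file and no default_n given")
        n = {locus: default_n for locus in loci}
    table = AlleleFrequencyTable.__new__(AlleleFrequencyTable)
    table.loci, table.n, table.freqs = loci, n, freqs
    table.published = published or None
    table.validate(tol=tol)
    return table


def write_frequency_table(table: AlleleFrequencyTable, path: str | Path,
                          decimals: int = 6) -> None:
    domain = sorted({a for locus in table.loci for a in table.freqs[locus]})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Allele", *table.loci])
        for a in domain:
            row = [str(a)]
            for locus in table.loci:
                f = table.freqs[locus].get(a)
                row.append("" if f is None else f"{f:.{decimals}f}".rstrip("0").rstrip("."))
            w.writerow(row)
        w.writerow(["n", *(table.n[locus] for locus in table.loci)])


def count_alleles(table: AlleleFrequencyTable) -> int:
    """Number of (locus, allele) pairs with positive frequency."""
    return sum(len(table.freqs[locus]) for locus in table.loci)


# ---------------------------------------------------------------------------
# Distance matrices

def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a labelled distance matrix from CSV or PHYLIP square format.

    CSV: header row of labels (leading blank cell), one labelled row per
    population; upper cells may be blank for lower-triangle input, in which
    case the matrix is mirrored.  PHYLIP: leading count line, then
    whitespace-separated label + values rows.  Asymmetries up to 1e-6 are
    averaged silently; beyond that a warning is issued before averaging.
    """
    text = Path(path).read_text()
    first = text.lstrip().splitlines()[0].strip()
    if "," in first:
        labels, rows = _read_square_csv(text)
    else:
        labels, rows = _read_phylip_square(text)
    mat = np.asarray(rows, dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"distance matrix is not square: {mat.shape}")
    asym = np.nanmax(np.abs(mat - mat.T)) if mat.size else 0.0
    if asym > 1e-6:
        warnings.warn(f"asymmetry up to {asym:.3g} symmetrized by averaging")
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(mat, ids=labels)


def _read_square_csv(text: str) -> tuple[list[str], list[list[float]]]:
    rows = list(csv.reader(io.StringIO(text)))
    labels = [c.strip() for c in rows[0][1:]]
    size = len(labels)
    mat = np.zeros((size, size))
    filled = np.zeros((size, size), dtype=bool)
    for i, row in enumerate(rows[1:size + 1]):
        for j, cell in enumerate(row[1:size + 1]):
            if str(cell).strip():
                mat[i, j] = float(cell)
                filled[i, j] = True
    # mirror triangle-only input
    mat = np.where(filled, mat, np.where(filled.T, mat.T, 0.0))
    return labels, mat.tolist()


def _read_phylip_square(text: str) -> tuple[list[str], list[list[float]]]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    size = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1:size + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:size + 1]])
    return labels, rows


def write_distance_matrix(dm: DistanceMatrix, path: str | Path,
                          phylip: bool = False, decimals: int = 6) -> None:
    ids = list(dm.ids)
    with open(path, "w", newline="") as fh:
        if phylip:
            fh.write(f"{len(ids)}\n")
            for i, label in enumerate(ids):
                vals = " ".join(f"{dm.data[i, j]:.{decimals}f}" for j in range(len(ids)))
                fh.write(f"{label} {vals}\n")
        else:
            w = csv.writer(fh)
            w.writerow([""] + ids)
            for i, label in enumerate(ids):
                w.writerow([label] + [f"{dm.data[i, j]:.{decimals}f}"
                                      for j in range(len(ids))])


# ---------------------------------------------------------------------------
# Trees

def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick (branch lengths, integer supports as
    internal-node labels).  The tree is written as rooted at its basal
    trifurcation, which is where the neighbor-joining builder leaves it;
    that rooting is arbitrary but stable.
    """
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue().strip()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source: str | Path) -> TreeNode:
    if isinstance(source, Path) or (isinstance(source, str) and not source.rstrip().endswith(";")):
        return TreeNode.read(str(source), format="newick")
    return TreeNode.read(io.StringIO(source), format="newick")


# ---------------------------------------------------------------------------
# Population sets (long CSV: population,locus,allele,frequency,n)

def read_population_set(path: str | Path) -> PopulationSet:
    df = pd.read_csv(path, dtype={"population": str, "locus": str, "allele": str})
    required = {"population", "locus", "allele", "frequency", "n"}
    if not required.issubset(df.columns):
        raise ValueError(f"population CSV needs columns {sorted(required)}")
    pops: dict[str, AlleleFrequencyTable] = {}
    for name, sub in df.groupby("population", sort=False):
        loci = list(dict.fromkeys(sub["locus"]))
        n = {}
        freqs: dict[str, dict[AlleleLabel, float]] = {}
        for locus, ls in sub.groupby("locus", sort=False):
            n[locus] = int(ls["n"].iloc[0])
            freqs[locus] = {AlleleLabel.parse(a): float(f)
                            for a, f in zip(ls["allele"], ls["frequency"])}
        pops[str(name)] = AlleleFrequencyTable(loci, n, freqs)
    return PopulationSet(pops)


def write_population_set(pops: PopulationSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["population", "locus", "allele", "frequency", "n"])
        for name, table in pops.populations.items():
            for locus in table.loci:
                for a, f in sorted(table.freqs[locus].items()):
                    w.writerow([name, locus, str(a), f"{f:.6f}", table.n[locus]])


# ---------------------------------------------------------------------------
# Packaged fixtures: the published Gorkha study tables

def _data_path(name: str):
    return resources.files("strpop.data").joinpath(name)


def load_gorkha_frequencies() -> AlleleFrequencyTable:
    """Allele frequencies and published summary rows for 15 autosomal STR
    loci typed in 98 Gorkha individuals (shipped transcription)."""
    with resources.as_file(_data_path("gorkha_str_frequencies.csv")) as p:
        return read_frequency_table(p)


def load_nei_da_matrix() -> DistanceMatrix:
    """Published Nei DA distance matrix between the Gorkha sample and 15
    comparison populations (shipped transcription)."""
    with resources.as_file(_data_path("nei_da_16pop.csv")) as p:
        return read_distance_matrix(p)
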