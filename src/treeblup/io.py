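"""Readers and writers for pedigree, genotype, trait and relationship-matrix files.

File formats are deliberately plain so that they are diffable and portable:

* pedigree — CSV with columns ``id, sire, dam`` and optional ``family,
  mating_type``; unknown parents are written as ``0``.
* genotypes — either a CSV (first column ``id``, one column per marker,
  entries 0/1/2 with ``NA``/empty/``-9`` for missing) or the PLINK ``.raw``
  dialect (six leading columns ``FID IID PAT MAT SEX PHENOTYPE`` then one
  column per marker, whitespace separated).
* traits — CSV with columns ``id, trial, replicate`` plus one column per
  trait; missing values allowed.
* relationship matrices — whitespace-delimited square block with the ids as
  both header row and first column.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

#: sentinel used for unknown parents in files and in :class:`Pedigree`
UNKNOWN = "0"

#: genotype symbols treated as missing on input
MISSING_SYMBOLS = {"NA", "", "-9", "NAN", "nan", "na"}

VALID_MATRIX_KINDS = {"A", "D_ped", "G_A", "G_D", "G_IBD", "Ga", "Gw", "H", "generic"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles)."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

class Pedigree:
    """An ordered pedigree: each individual with its sire and dam.

    Individuals are stored in a topological order (parents before
    offspring).  Parents that appear only in the sire/dam columns are
    added implicitly as founders.  Unknown parents are represented by
    :data:`UNKNOWN`.

    Parameters
    ----------
    ids, sires, dams : sequences of str
        Parallel arrays of individual, sire and dam labels.
    family, mating_type : mappings, optional
        Per-individual metadata (family label, ``OP``/``CP``/``POLYMIX``).
    """

    def __init__(self, ids, sires, dams, family=None, mating_type=None):
        ids = [str(i) for i in ids]
        sires = [str(s) for s in sires]
        dams = [str(d) for d in dams]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)
            dup = dup[dup.duplicated()].iloc[0]
            raise PedigreeError(f"duplicate individual id: {dup!r}")
        if UNKNOWN in ids:
            raise PedigreeError(f"id equal to the unknown sentinel {UNKNOWN!r}")

        sire_of = dict(zip(ids, sires))
        dam_of = dict(zip(ids, dams))
        # implicit founders: parents never listed as individuals
        known = set(ids)
        implicit = []
        for p in [*sires, *dams]:
            if p != UNKNOWN and p not in known:
                known.add(p)
                implicit.append(p)
        all_ids = implicit + ids
        for p in implicit:
            sire_of[p] = UNKNOWN
            dam_of[p] = UNKNOWN

        g = nx.DiGraph()
        g.add_nodes_from(all_ids)
        for child in all_ids:
            for parent in (sire_of[child], dam_of[child]):
                if parent != UNKNOWN:
                    g.add_edge(parent, child)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle is not None:
            path = " -> ".join([e[0] for e in cycle] + [cycle[-1][1]])
            raise PedigreeError(f"pedigree cycle detected: {path}")

        pos = {ind: k for k, ind in enumerate(all_ids)}
        order = list(nx.lexicographical_topological_sort(g, key=pos.get))

        self.ids: list[str] = order
        self.index: dict[str, int] = {ind: k for k, ind in enumerate(order)}
        self.sire_idx = np.array(
            [self.index.get(sire_of[i], -1) if sire_of[i] != UNKNOWN else -1
             for i in order], dtype=np.int64)
        self.dam_idx = np.array(
            [self.index.get(dam_of[i], -1) if dam_of[i] != UNKNOWN else -1
             for i in order], dtype=np.int64)
        self.family = dict(family or {})
        self.mating_type = dict(mating_type or {})

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, ind) -> bool:
        return str(ind) in self.index

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return (set(self.ids) == set(other.ids)
                and all(self.parents_of(i) == other.parents_of(i) for i in self.ids))

    def parents_of(self, ind) -> tuple[str, str]:
        """Return ``(sire, dam)`` labels of *ind* (:data:`UNKNOWN` allowed)."""
        k = self.index[str(ind)]
        s = self.ids[self.sire_idx[k]] if self.sire_idx[k] >= 0 else UNKNOWN
        d = self.ids[self.dam_idx[k]] if self.dam_idx[k] >= 0 else UNKNOWN
        return s, d

    @property
    def founders(self) -> list[str]:
        return [i for k, i in enumerate(self.ids)
                if self.sire_idx[k] < 0 and self.dam_idx[k] < 0]

    @property
    def parent_ids(self) -> set[str]:
        """Ids appearing as sire or dam of at least one individual."""
        out = set()
        for k in range(len(self.ids)):
            if self.sire_idx[k] >= 0:
                out.add(self.ids[self.sire_idx[k]])
            if self.dam_idx[k] >= 0:
                out.add(self.ids[self.dam_idx[k]])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in self.ids:
            s, d = self.parents_of(i)
            rows.append((i, s, d, self.family.get(i, ""), self.mating_type.get(i, "")))
        return pd.DataFrame(rows, columns=["id", "sire", "dam", "family", "mating_type"])

    def with_parents(self, ind, sire, dam) -> "Pedigree":
        """Return a copy in which *ind*'s recorded parents are replaced."""
        df = self.to_frame()
        df.loc[df["id"] == str(ind), ["sire", "dam"]] = [str(sire), str(dam)]
        return Pedigree(df["id"], df["sire"], df["dam"],
                        family=self.family, mating_type=self.mating_type)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree file must have columns {sorted(required)}")
    for col in ("sire", "dam"):
        df[col] = df[col].replace({"": UNKNOWN, "NA": UNKNOWN})
    family = dict(zip(df["id"], df["family"])) if "family" in df else None
    mating = dict(zip(df["id"], df["mating_type"])) if "mating_type" in df else None
    return Pedigree(df["id"], df["sire"], df["dam"], family=family, mating_type=mating)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype matrix, coded 0/1/2 with NaN missing.

    ``calls`` may hold fractional values after mean imputation; raw input
    is validated to {0, 1, 2, missing}.
    """

    ids: list[str]
    markers: list[str]
    calls: np.ndarray  # float64, shape (n_ids, n_markers), NaN = missing

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.markers = [str(m) for m in self.markers]
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.ids), len(self.markers)):
            raise ValueError("calls shape does not match ids x markers")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def p(self) -> np.ndarray:
        """Allele frequency of the counted allele per marker (non-missing calls)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0

    @property
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    @property
    def maf(self) -> np.ndarray:
        p = self.p
        return np.minimum(p, 1.0 - p)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.calls).any()

    def subset(self, ids=None, markers=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals)
        cols = np.arange(self.n_markers)
        if ids is not None:
            idx = {v: k for k, v in enumerate(self.ids)}
            rows = np.array([idx[str(i)] for i in ids])
        if markers is not None:
            midx = {v: k for k, v in enumerate(self.markers)}
            cols = np.array([midx[str(m)] for m in markers])
        return GenotypeMatrix(
            [self.ids[r] for r in rows], [self.markers[c] for c in cols],
            self.calls[np.ix_(rows, cols)])

    def __eq__(self, other):
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.ids == other.ids and self.markers == other.markers
                and np.allclose(self.calls, other.calls, equal_nan=True))


def _parse_genotype_block(raw: pd.DataFrame, origin: str) -> np.ndarray:
    vals = raw.astype(str).map(str.strip)
    missing = vals.isin(MISSING_SYMBOLS).to_numpy()
    numeric = vals.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(numeric) & ~missing
    ok = np.isin(numeric, (0.0, 1.0, 2.0)) | missing
    if bad.any() or not ok.all():
        r, c = np.argwhere(bad if bad.any() else ~ok)[0]
        raise ValueError(
            f"{origin}: non-genotype symbol {vals.iat[r, c]!r} at row {r + 1}, "
            f"column {c + 1}")
    numeric[missing] = np.nan
    return numeric


def read_genotypes(path, dialect: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix from CSV or PLINK ``.raw`` dialect."""
    if dialect == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        ids = df.iloc[:, 0].tolist()
        markers = list(df.columns[1:])
        calls = _parse_genotype_block(df.iloc[:, 1:], str(path))
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[:6]) != lead:
            raise ValueError(f"{path}: not a PLINK .raw header (expected {lead})")
        ids = df["IID"].tolist()
        markers = list(df.columns[6:])
        calls = _parse_genotype_block(df.iloc[:, 6:], str(path))
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    return GenotypeMatrix(ids, markers, calls)


def write_genotypes(g: GenotypeMatrix, path, dialect: str = "csv") -> None:
    def fmt(x):
        if np.isnan(x):
            return "NA"
        return str(int(x)) if float(x).is_integer() else repr(x)

    body = [[fmt(x) for x in row] for row in g.calls]
    if dialect == "csv":
        df = pd.DataFrame(body, columns=g.markers)
        df.insert(0, "id", g.ids)
        df.to_csv(path, index=False)
    elif dialect == "plink_raw":
        df = pd.DataFrame(body, columns=g.markers)
        for col, val in zip(("PHENOTYPE", "SEX", "MAT", "PAT"), ("-9", "0", "0", "0")):
            df.insert(0, col, val)
        df.insert(0, "IID", g.ids)
        df.insert(0, "FID", g.ids)
        df.to_csv(path, sep=" ", index=False)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------

@dataclass
class RelationshipMatrix:
    """Labeled square symmetric relationship matrix with a kind tag."""

    ids: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix is not square over its ids")
        if self.kind not in VALID_MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > 1e-8:
            raise ValueError(f"matrix asymmetric (max |M - M'| = {asym:.3g})")
        # exact symmetry, so downstream eigendecompositions are clean
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.ids)

    def loc(self, i, j) -> float:
        return float(self.values[self.ids.index(str(i)), self.ids.index(str(j))])

    def reorder(self, ids) -> "RelationshipMatrix":
        idx = {v: k for k, v in enumerate(self.ids)}
        sel = np.array([idx[str(i)] for i in ids], dtype=np.intp)
        return RelationshipMatrix([str(i) for i in ids],
                                  self.values[np.ix_(sel, sel)], self.kind)

    def submatrix(self, ids) -> "RelationshipMatrix":
        return self.reorder(ids)


def read_matrix(path, kind: str = "generic") -> RelationshipMatrix:
    """Read a whitespace square matrix with id header row and column.

    Asymmetries below 1e-6 are silently symmetrized by averaging with the
    transpose; anything larger is an error.
    """
    df = pd.read_csv(path, sep=r"\s+", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix block is not square {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row ids do not match column ids")
    m = df.to_numpy(dtype=float)
    asym = np.abs(m - m.T).max(initial=0.0)
    if asym >= 1e-6:
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance ({asym:.3g} >= 1e-6)")
    m = 0.5 * (m + m.T)
    return RelationshipMatrix(list(df.index.astype(str)), m, kind=kind)


def write_matrix(m: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(m.values, index=m.ids, columns=m.ids)
    with open(path, "w") as fh:
        fh.write(df.to_csv(sep=" ", float_format="%.10g"))


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def read_traits(path) -> pd.DataFrame:
    """Read a trait table: columns ``id, trial[, replicate]`` + trait columns."""
    df = pd.read_csv(path)
    if "id" not in df.columns or "trial" not in df.columns:
        raise ValueError(f"{path}: trait table needs 'id' and 'trial' columns")
    df["id"] = df["id"].astype(str)
    df["trial"] = df["trial"].astype(str)
    for col in trait_columns(df):
        bad = np.isinf(df[col].to_numpy(dtype=float))
        if bad.any():
            raise ValueError(f"{path}: non-finite value in trait {col!r}")
    return df


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index=False)


def trait_columns(traits: pd.DataFrame) -> list[str]:
    """Names of the trait-value columns of a trait table."""
    return [c for c in traits.columns if c not in ("id", "trial", "replicate", "family")]
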