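"""Readers/writers for the plain-text formats the pipeline consumes.

Pedigrees are ``animal,sire,dam`` CSV ("0" or empty = unknown parent);
genotypes are a whitespace-delimited additive-coded table paired with a
PLINK-style 4-column ``.map`` (chromosome, snp_id, cM — ignored —, bp);
phenotypes are long-format CSV; gene coordinates come from BED (0-based
half-open on disk, converted to 1-based inclusive in memory).  All
outputs are TSV with headers.
"""

from __future__ import annotations

from collections import deque
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING_CALL,
    UNKNOWN_PARENT,
    GenotypeSet,
    Pedigree,
    PhenotypeTable,
)

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_bed_genes",
    "casein_index",
    "load_reference_windows",
]


def _normalize_parent(value) -> str:
    if pd.isna(value):
        return UNKNOWN_PARENT
    s = str(value).strip()
    return UNKNOWN_PARENT if s in ("", "0") else s


def read_pedigree(path) -> Pedigree:
    """Read an ``animal,sire,dam`` CSV and return a topologically sorted
    :class:`Pedigree`.

    Parents that appear only in the sire/dam columns are auto-inserted as
    founders.  A parentage cycle is a hard error naming one member of the
    cycle; so is a duplicate animal id.
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise ValueError(f"pedigree file must have columns animal,sire,dam; got {list(df.columns)}")

    animals = [str(a).strip() for a in df["animal"]]
    if len(set(animals)) != len(animals):
        dup = next(a for a in animals if animals.count(a) > 1)
        raise ValueError(f"duplicate animal id {dup!r} in pedigree file")

    parents = {a: (_normalize_parent(s), _normalize_parent(d))
               for a, s, d in zip(animals, df["sire"], df["dam"])}

    # auto-insert referenced-but-undeclared parents as founders
    declared = set(parents)
    for sire, dam in list(parents.values()):
        for p in (sire, dam):
            if p != UNKNOWN_PARENT and p not in declared:
                parents[p] = (UNKNOWN_PARENT, UNKNOWN_PARENT)
                declared.add(p)

    return _toposort(parents)


def _toposort(parents: dict[str, tuple[str, str]]) -> Pedigree:
    """Kahn's algorithm over the parent->offspring DAG; stable order."""
    children: dict[str, list[str]] = {a: [] for a in parents}
    indeg = {a: 0 for a in parents}
    for animal, (sire, dam) in parents.items():
        for p in {sire, dam} - {UNKNOWN_PARENT}:
            children[p].append(animal)
            indeg[animal] += 1
    queue = deque(a for a in parents if indeg[a] == 0)
    ordered: list[str] = []
    while queue:
        a = queue.popleft()
        ordered.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(ordered) != len(parents):
        member = next(a for a in parents if indeg[a] > 0)
        raise ValueError(f"pedigree contains a parentage cycle involving {member!r}")
    return Pedigree(tuple((a, parents[a][0], parents[a][1]) for a in ordered))


def write_pedigree(ped: Pedigree, path) -> None:
    pd.DataFrame(ped.records, columns=["animal", "sire", "dam"]).to_csv(path, index=False)


def read_genotypes(raw_path, map_path) -> GenotypeSet:
    """Read an additive-coded genotype table plus its marker map.

    ``raw_path``: whitespace-delimited, one row per animal — first column
    the animal id, then one 0/1/2/NA column per SNP in map row order.
    ``map_path``: PLINK-style whitespace-delimited 4 columns
    (chromosome, snp_id, cM, bp); the cM column is ignored.
    Markers come back sorted by (chromosome, bp, snp_id) with calls
    permuted in lockstep.
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chromosome", "snp_id", "cm", "position_bp"], dtype=str)
    markers = pd.DataFrame({
        "snp_id": mp["snp_id"].astype(str),
        "chromosome": mp["chromosome"].astype(str),
        "position_bp": mp["position_bp"].astype(np.int64),
    })
    if (markers["position_bp"] < 1).any():
        raise ValueError("marker positions must be >= 1 (1-based bp)")

    raw = pd.read_csv(raw_path, sep=r"\s+", header=None, dtype=str, keep_default_na=False)
    if raw.shape[1] - 1 != len(markers):
        raise ValueError(
            f"genotype file has {raw.shape[1] - 1} SNP columns but map lists {len(markers)} markers"
        )
    animal_ids = raw.iloc[:, 0].astype(str).tolist()
    body = raw.iloc[:, 1:].to_numpy(dtype=object)
    calls = np.full(body.shape, MISSING_CALL, dtype=np.int16)
    for code in ("0", "1", "2"):
        calls[body == code] = int(code)
    valid = np.isin(body, ("0", "1", "2", "NA", "na", "nan"))
    if not valid.all():
        ai, mi = np.argwhere(~valid)[0]
        raise ValueError(
            f"invalid genotype code {body[ai, mi]!r} at "
            f"(animal {animal_ids[ai]!r}, snp {markers['snp_id'].iloc[mi]!r})"
        )
    return GenotypeSet(animal_ids=animal_ids, markers=markers, calls=calls)


def write_genotypes(g: GenotypeSet, raw_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for row in g.markers.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}\n")
    with open(raw_path, "w") as fh:
        for animal, row in zip(g.animal_ids, g.calls):
            cells = ["NA" if c == MISSING_CALL else str(int(c)) for c in row]
            fh.write(animal + "\t" + "\t".join(cells) + "\n")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, dtype={"animal_id": str, "trait_name": str,
                                  "farm": str, "lactation": str, "parity": str})
    return PhenotypeTable(df)


def write_phenotypes(ph: PhenotypeTable, path) -> None:
    ph.data.to_csv(path, index=False)


def read_bed_genes(path) -> pd.DataFrame:
    """Read gene coordinates from BED (chrom, chromStart, chromEnd, name).

    BED is 0-based half-open on disk; returned frame uses 1-based
    inclusive ``start_bp``/``end_bp`` matching the rest of the pipeline.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed BED line {lineno}: need >= 4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"malformed BED line {lineno}: non-integer coordinates") from None
            if end <= start:
                raise ValueError(f"malformed BED line {lineno}: end <= start")
            rows.append((parts[0], start + 1, end, parts[3]))
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "gene_id"])


def casein_index(as1: float, as2: float, b: float, k: float,
                 ala: float, blg: float) -> float:
    """Casein index: 100 x total casein / (total casein + total whey).

    Inputs are the six milk-protein fractions in wt/wt % — the four
    caseins (alpha-s1, alpha-s2, beta, kappa) and the two whey proteins
    (alpha-lactalbumin, beta-lactoglobulin).  Scale-invariant: only the
    casein/whey proportion matters.
    """
    values = np.array([as1, as2, b, k, ala, blg], dtype=float)
    if (values < 0).any():
        raise ValueError("protein fractions must be non-negative")
    casein = values[:4].sum()
    total = values.sum()
    if total == 0:
        raise ValueError("casein index undefined for all-zero protein fractions")
    return 100.0 * casein / total


def load_reference_windows() -> pd.DataFrame:
    """Load the bundled reference table of significant 5-SNP windows from
    a published Holstein milk-protein association study.

    Columns: trait, window_id, chromosome, start_bp, end_bp, genes,
    ve_percent (percent of additive genetic variance explained).  Used
    for region-aggregation demos and regression tests of the reporting
    operations.
    """
    path = Path(__file__).parent / "data" / "holstein_milk_protein_windows.tsv"
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})
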