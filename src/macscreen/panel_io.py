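"""Readers, writers and the panel data model.

The pipeline works on a biparental recombinant inbred panel: every strain is
essentially homozygous at every marker, so genotype calls are coded by
*parental origin* rather than by nucleotide:

* ``P1`` — the reference-parent allele (N2-like), stored as ``0``
* ``P2`` — the alternative-parent allele (Hawaii/CB4856-like), stored as ``1``
* ``MISSING`` — no call, stored as ``-1``

Genotype TSV dialect (no community standard exists for parental-origin
matrices, so we define one): optional ``#``-prefixed comment lines, then a
header row ``strain<TAB><marker ids...>``, one row per strain, cells in
``{N2, HW, NA}`` (aliases ``0/1/NA`` accepted).  The marker map is a separate
TSV with columns ``marker_id``, ``chromosome``, ``position`` (1-based bp).

PLINK ``.ped``/``.map`` text files are accepted read-only.  Because a bare
``.ped`` does not say which nucleotide came from which parent, the
lexicographically smaller allele symbol at each marker is taken as P1 unless
an explicit ``parent_alleles`` mapping is supplied.  Heterozygous calls are
coded MISSING: the panel model is strictly biallelic-homozygous.

All genomic coordinates are 1-based inclusive internally (WormBase GFF
convention); BED input is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

P1: int = 0
P2: int = 1
MISSING: int = -1

#: default cell symbols for the genotype TSV dialect
TSV_SYMBOLS = {"N2": P1, "HW": P2, "NA": MISSING, "0": P1, "1": P2}
_CODE_TO_SYMBOL = {P1: "N2", P2: "HW", MISSING: "NA"}


class PanelFormatError(ValueError):
    """Malformed or inconsistent input file."""


def _check_marker_map(markers: pd.DataFrame) -> pd.DataFrame:
    required = {"marker_id", "chromosome", "position"}
    missing_cols = required - set(markers.columns)
    if missing_cols:
        raise PanelFormatError(f"marker map missing columns: {sorted(missing_cols)}")
    if markers["marker_id"].duplicated().any():
        dups = markers.loc[markers["marker_id"].duplicated(), "marker_id"].tolist()
        raise PanelFormatError(f"duplicate marker IDs: {dups[:5]}")
    if (markers["position"] < 1).any():
        raise PanelFormatError("marker positions must be >= 1 (1-based)")
    out = markers.reset_index(drop=True).copy()
    out["position"] = out["position"].astype(np.int64)
    out["chromosome"] = out["chromosome"].astype(str)
    return out


@dataclass
class GenotypePanel:
    """A strain x marker matrix of parental-origin calls plus its marker map.

    Parameters
    ----------
    strain_ids
        Unique strain names, one per row of ``calls``.
    markers
        Marker map with columns ``marker_id``, ``chromosome``, ``position``,
        ordered as the columns of ``calls``.
    calls
        ``int8`` array of shape ``(n_strains, n_markers)`` over
        ``{P1, P2, MISSING}``.
    """

    strain_ids: list[str]
    markers: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.strain_ids = [str(s) for s in self.strain_ids]
        if len(set(self.strain_ids)) != len(self.strain_ids):
            seen: set[str] = set()
            dup = [s for s in self.strain_ids if s in seen or seen.add(s)]
            raise PanelFormatError(f"duplicate strain IDs: {dup[:5]}")
        self.markers = _check_marker_map(self.markers)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.strain_ids), len(self.markers)):
            raise PanelFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.strain_ids)} strains x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (P1, P2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelFormatError(
                f"invalid call code {self.calls[i, j]} at strain "
                f"{self.strain_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["marker_id"].tolist()

    def strain_index(self, strain_id: str) -> int:
        try:
            return self.strain_ids.index(str(strain_id))
        except ValueError:
            raise KeyError(f"unknown strain {strain_id!r}") from None

    def marker_index(self, marker_id: str) -> int:
        ids = self.markers["marker_id"]
        hits = np.flatnonzero(ids.to_numpy() == str(marker_id))
        if hits.size == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(hits[0])

    def subset_strains(self, strain_ids: Sequence[str]) -> "GenotypePanel":
        idx = [self.strain_index(s) for s in strain_ids]
        return GenotypePanel(
            strain_ids=[self.strain_ids[i] for i in idx],
            markers=self.markers.copy(),
            calls=self.calls[idx, :].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Calls as a strains x markers DataFrame of symbols (N2/HW/NA)."""
        sym = np.vectorize(_CODE_TO_SYMBOL.get)(self.calls)
        return pd.DataFrame(sym, index=self.strain_ids, columns=self.marker_ids)


# ---------------------------------------------------------------------------
# genotype I/O


def _read_table(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kw)


def read_genotypes(
    path: str | Path,
    format: str = "tsv",
    map_path: str | Path | None = None,
    symbols: Mapping[str, int] | None = None,
    parent_alleles: Mapping[str, tuple[str, str]] | None = None,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Read a genotype matrix and its marker map.

    ``format="tsv"`` reads the package's genotype dialect; ``map_path``
    defaults to ``<path stem>.map.tsv`` next to the genotype file.
    ``format="pedmap"`` reads PLINK text ``.ped``/``.map``; ``path`` may be
    the ``.ped`` file or the common prefix.

    Returns the panel and its marker map (also attached to the panel).
    """
    path = Path(path)
    if format == "tsv":
        panel = _read_genotypes_tsv(path, map_path, symbols or TSV_SYMBOLS)
    elif format == "pedmap":
        panel = _read_pedmap(path, parent_alleles)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    _warn_uninformative(panel)
    return panel, panel.markers


def _warn_uninformative(panel: GenotypePanel) -> None:
    all_missing = (panel.calls == MISSING).all(axis=0)
    if all_missing.any():
        n = int(all_missing.sum())
        logger.warning("%d marker(s) have no non-missing call (uninformative)", n)


def _read_genotypes_tsv(
    path: Path, map_path: str | Path | None, symbols: Mapping[str, int]
) -> GenotypePanel:
    df = _read_table(path)
    if df.shape[1] < 2:
        raise PanelFormatError(f"{path}: expected strain column plus >=1 marker")
    strain_col = df.columns[0]
    marker_ids = list(df.columns[1:])
    if len(set(marker_ids)) != len(marker_ids):
        raise PanelFormatError(f"{path}: duplicate marker IDs in header")
    strains = df[strain_col].astype(str).tolist()

    cells = df.iloc[:, 1:]
    isna = cells.isna().to_numpy()
    vals = cells.to_numpy(dtype=object)
    calls = np.full(vals.shape, MISSING, dtype=np.int8)
    known = isna.copy()  # empty cells are MISSING
    for sym, code in symbols.items():
        hit = (vals == sym) & ~isna
        calls[hit] = code
        known |= hit
    if not known.all():
        i, j = np.argwhere(~known)[0]
        raise PanelFormatError(
            f"{path}: unknown allele symbol {vals[i, j]!r} at strain "
            f"{strains[i]!r}, marker {marker_ids[j]!r}"
        )

    if map_path is None:
        cand = path.with_suffix(".map.tsv")
        map_path = cand if cand.exists() else None
    if map_path is not None:
        markers = read_marker_map(map_path)
        order = {m: i for i, m in enumerate(marker_ids)}
        unknown = set(markers["marker_id"]) ^ set(marker_ids)
        if unknown:
            raise PanelFormatError(
                f"marker map and genotype header disagree on: {sorted(unknown)[:5]}"
            )
        # marker order follows the map file
        idx = [order[m] for m in markers["marker_id"]]
        calls = calls[:, idx]
    else:
        # placeholder map: one synthetic chromosome, ordinal positions
        markers = pd.DataFrame(
            {
                "marker_id": marker_ids,
                "chromosome": "un",
                "position": np.arange(1, len(marker_ids) + 1),
            }
        )
    return GenotypePanel(strain_ids=strains, markers=markers, calls=calls)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    df = df.rename(columns={c: c.lower() for c in df.columns})
    df["position"] = df["position"].astype(np.int64)
    return _check_marker_map(df[["marker_id", "chromosome", "position"]])


def _read_pedmap(
    path: Path, parent_alleles: Mapping[str, tuple[str, str]] | None
) -> GenotypePanel:
    ped = path if path.suffix == ".ped" else path.with_suffix(".ped")
    mp = ped.with_suffix(".map")
    if not ped.exists() or not mp.exists():
        raise FileNotFoundError(f"need both {ped} and {mp}")

    map_rows = []
    for line in mp.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 4:
            raise PanelFormatError(f"{mp}: bad map line {line!r}")
        map_rows.append((f[1], f[0], int(f[3])))
    markers = _check_marker_map(
        pd.DataFrame(map_rows, columns=["marker_id", "chromosome", "position"])
    )
    n_mark = len(markers)

    strains: list[str] = []
    geno_pairs: list[list[tuple[str, str]]] = []
    for line in ped.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) != 6 + 2 * n_mark:
            raise PanelFormatError(
                f"{ped}: line for {f[1] if len(f) > 1 else '?'} has "
                f"{len(f)} fields, expected {6 + 2 * n_mark}"
            )
        strains.append(f[1])
        geno_pairs.append([(f[6 + 2 * j], f[7 + 2 * j]) for j in range(n_mark)])

    calls = np.full((len(strains), n_mark), MISSING, dtype=np.int8)
    for j, marker in enumerate(markers["marker_id"]):
        if parent_alleles and marker in parent_alleles:
            p1_sym, p2_sym = (str(a) for a in parent_alleles[marker])
        else:
            observed = sorted(
                {a for pairs in geno_pairs for a in pairs[j] if a != "0"}
            )
            if len(observed) > 2:
                raise PanelFormatError(
                    f"marker {marker!r}: more than two alleles {observed}"
                )
            p1_sym = observed[0] if observed else "0"
            p2_sym = observed[1] if len(observed) > 1 else None
        for i, pairs in enumerate(geno_pairs):
            a, b = pairs[j]
            if a == "0" or b == "0" or a != b:  # no-call or heterozygous
                continue
            if a == p1_sym:
                calls[i, j] = P1
            elif p2_sym is not None and a == p2_sym:
                calls[i, j] = P2
            else:
                raise PanelFormatError(
                    f"marker {marker!r}, strain {strains[i]!r}: "
                    f"allele {a!r} not in parent map"
                )
    return GenotypePanel(strain_ids=strains, markers=markers, calls=calls)


def write_genotypes(
    panel: GenotypePanel,
    path: str | Path,
    map_path: str | Path | None = None,
    header_comments: Mapping[str, object] | None = None,
) -> None:
    """Write the genotype TSV dialect (plus marker map TSV if requested).

    ``header_comments`` key/value pairs are recorded as ``# key=value`` lines
    so outputs carry their generating parameters and seed.
    """
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in (header_comments or {}).items()]
    lines.append("strain\t" + "\t".join(panel.marker_ids))
    frame = panel.to_frame()
    for strain, row in zip(frame.index, frame.to_numpy()):
        lines.append(str(strain) + "\t" + "\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    if map_path is not None:
        write_marker_map(panel.markers, map_path)


def write_marker_map(markers: pd.DataFrame, path: str | Path) -> None:
    markers.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trait / expression / annotation


def read_trait_table(path: str | Path, stratum_column: str | None = None) -> pd.DataFrame:
    """Read a strain -> trait TSV with columns ``strain_id``, ``trait_value``
    and optionally a stratum column (e.g. the npr-1 background allele)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    df = df.rename(columns={df.columns[0]: "strain_id"})
    if "trait_value" not in df.columns:
        df = df.rename(columns={df.columns[1]: "trait_value"})
    vals = pd.to_numeric(df["trait_value"], errors="coerce")
    bad = ~np.isfinite(vals.to_numpy(dtype=float))
    if bad.any():
        loc = df.index[bad][0]
        raise PanelFormatError(
            f"{path}: non-numeric or non-finite trait value "
            f"{df.loc[loc, 'trait_value']!r} for strain {df.loc[loc, 'strain_id']!r}"
        )
    df["trait_value"] = vals.astype(float)
    if df["strain_id"].duplicated().any():
        raise PanelFormatError(f"{path}: duplicate strain IDs in trait table")
    if stratum_column is not None and stratum_column not in df.columns:
        raise PanelFormatError(f"{path}: no stratum column {stratum_column!r}")
    return df


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x strain expression TSV (genes as rows, first column gene_id).

    Missing cells (empty or ``NA``) stay NaN until imputation.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise PanelFormatError(
            f"{path}: empty expression matrix (need >=1 gene x >=2 strains)"
        )
    if df.index.duplicated().any():
        raise PanelFormatError(f"{path}: duplicate gene IDs")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise PanelFormatError(f"{path}: non-numeric expression value ({exc})") from exc
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df.columns = df.columns.astype(str)
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_annotation(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read gene coordinates from GFF3 or BED.

    Returns a DataFrame with ``gene_id``, ``chromosome``, ``start``, ``end``
    (1-based inclusive) and ``strand``.  BED's 0-based half-open intervals
    are converted on read.
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    if format == "gff3":
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise PanelFormatError(f"{path}: bad GFF3 line {line!r}")
            if f[2] not in {"gene", "protein_coding_gene", "pseudogene"}:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("gene_id", attrs.get("Name")))
            if gene_id is None:
                raise PanelFormatError(f"{path}: gene feature without ID: {line!r}")
            rows.append((gene_id.removeprefix("gene:"), f[0], int(f[3]), int(f[4]), f[6]))
    elif format == "bed":
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise PanelFormatError(f"{path}: BED line needs >=4 fields: {line!r}")
            strand = f[5] if len(f) >= 6 else "+"
            # BED is 0-based half-open; internal convention is 1-based inclusive
            rows.append((f[3], f[0], int(f[1]) + 1, int(f[2]), strand))
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    ann = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])
    if ann.empty:
        raise PanelFormatError(f"{path}: no gene records found")
    if ann["gene_id"].duplicated().any():
        raise PanelFormatError(f"{path}: duplicate gene IDs in annotation")
    if (ann["start"] > ann["end"]).any():
        raise PanelFormatError(f"{path}: gene with start > end")
    if not ann["strand"].isin(["+", "-"]).all():
        raise PanelFormatError(f"{path}: strand must be + or -")
    return ann


def write_gene_annotation_bed(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    lines = [
        f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.gene_id}\t.\t{r.strand}"
        for r in out.itertuples()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def intersect_strains(
    panel: GenotypePanel,
    trait: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
) -> list[str]:
    """Strains common to panel, trait table and expression matrix.

    Returned in panel order, so the result does not depend on the input file
    row orders.  Strains present in one table but absent from another are
    logged and excluded from joined analyses (they stay in their own tables).
    """
    common = set(panel.strain_ids)
    if trait is not None:
        common &= set(trait["strain_id"].astype(str))
    if expression is not None:
        common &= set(map(str, expression.columns))
    dropped = set(panel.strain_ids) - common
    if dropped:
        logger.info("strain intersection drops %d panel strain(s)", len(dropped))
    return [s for s in panel.strain_ids if s in common]
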