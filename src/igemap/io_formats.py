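"""Readers, writers and validated containers for the mapping pipeline.

Three tabular artefacts flow through the pipeline:

* a GeneNetwork-style ``.geno`` file holding the recombinant-inbred (RI)
  panel marker map and per-line biallelic calls (``B`` = C57BL/6J allele,
  ``D`` = DBA/2J allele, ``H``/``U`` = missing),
* a family phenotype CSV with one row per family x day x role x trait plus
  the litter/maternal covariates, and
* the final locus table (TSV + JSON) mirroring the classic
  direct-effects-first QTL report layout.

All readers validate eagerly and raise :class:`ParseError` with the
offending line/row identified; nothing is silently coerced.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "TRAITS_BY_ROLE",
    "DAYS",
    "COVARIATES",
    "ParseError",
    "GeneticMap",
    "GenotypeMatrix",
    "FamilyTable",
    "read_geno",
    "write_geno",
    "read_pheno",
    "write_pheno",
    "write_locus_table",
    "read_locus_json",
]

#: Social roles within a cross-fostered family. BXD pups carry the variable
#: genotype (direct effects); B6 pups and the B6 mother are genetically
#: uniform, so their trait variation maps to the BXD half-litter genotype
#: (indirect effects).
ROLES = ("BXD_offspring", "B6_offspring", "mother")

#: Valid behavioural traits per role.
TRAITS_BY_ROLE = {
    "BXD_offspring": ("solicitation", "sucking", "activity"),
    "B6_offspring": ("solicitation", "sucking", "activity"),
    "mother": ("suckling", "activity"),
}

#: Postpartum observation days.
DAYS = (6, 10, 14)

#: Litter/maternal covariates removed before mapping, in their declared
#: order (used to break ties during backward elimination).
COVARIATES = (
    "maternal_bodyweight",
    "avg_B6_pup_weight",
    "B6_litter_size",
    "avg_BXD_pup_weight",
    "BXD_litter_size",
    "batch",
)

PHENO_COLUMNS = (
    "family_id",
    "line_id",
    "day",
    "role",
    "trait",
    "value",
) + COVARIATES

_GENO_CODES = {"B": 0.0, "D": 1.0, "H": np.nan, "U": np.nan}
_CODE_FOR_CALL = {0.0: "B", 1.0: "D"}


class ParseError(ValueError):
    """A file violated the expected dialect; message locates the problem."""


def chrom_sort_key(label: str) -> tuple[int, str]:
    """Canonical chromosome order: numeric labels first, then X, then rest."""
    s = str(label)
    if s.isdigit():
        return (0, f"{int(s):04d}")
    if s.upper() == "X":
        return (1, "X")
    return (2, s)


# ---------------------------------------------------------------------------
# genetic map + genotypes
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Marker grid of an RI panel: name, chromosome, cM and Mb per marker.

    Markers are stored sorted by (chromosome, cM); names must be unique and
    positions non-negative with cM non-decreasing within a chromosome.
    """

    table: pd.DataFrame  # columns: marker, chromosome, cM, Mb

    def __post_init__(self) -> None:
        required = {"marker", "chromosome", "cM", "Mb"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"genetic map missing columns: {sorted(missing)}")
        tbl = self.table.copy()
        tbl["chromosome"] = tbl["chromosome"].astype(str)
        tbl = tbl.sort_values(
            by=["chromosome", "cM"],
            key=lambda col: col.map(chrom_sort_key) if col.name == "chromosome" else col,
            kind="stable",
        ).reset_index(drop=True)
        if tbl["marker"].duplicated().any():
            dups = tbl.loc[tbl["marker"].duplicated(), "marker"].tolist()
            raise ParseError(f"duplicate marker names: {dups}")
        if (tbl["cM"] < 0).any() or (tbl["Mb"] < 0).any():
            raise ValueError("marker positions must be non-negative")
        self.table = tbl

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.table["chromosome"]:
            seen.setdefault(c, None)
        return list(seen)

    def marker_index(self, name: str) -> int:
        idx = self.table.index[self.table["marker"] == name]
        if len(idx) == 0:
            raise KeyError(f"marker {name!r} not in map")
        return int(idx[0])

    def chrom_slice(self, chromosome: str) -> pd.DataFrame:
        sub = self.table[self.table["chromosome"] == str(chromosome)]
        if sub.empty:
            raise KeyError(f"chromosome {chromosome!r} not in map")
        return sub

    def cm_to_mb(self, chromosome: str, cm: np.ndarray | float) -> np.ndarray | float:
        """Interpolate physical Mb from genetic cM along one chromosome."""
        sub = self.chrom_slice(chromosome)
        return np.interp(cm, sub["cM"].to_numpy(), sub["Mb"].to_numpy())


@dataclass
class GenotypeMatrix:
    """Per-line biallelic calls (0 = B, 1 = D, NaN = missing) on a map."""

    line_ids: list[str]
    calls: np.ndarray  # shape (n_lines, n_markers), float with NaN missing
    gmap: GeneticMap

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.line_ids), self.gmap.n_markers):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {self.gmap.n_markers} markers"
            )
        ok = np.isnan(self.calls) | (self.calls == 0.0) | (self.calls == 1.0)
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"calls must be 0, 1 or NaN; found {bad}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def line_index(self, line_id: str) -> int:
        try:
            return self.line_ids.index(str(line_id))
        except ValueError:
            raise KeyError(f"line {line_id!r} not in genotype matrix") from None

    def marker_calls(self, marker: str) -> pd.Series:
        """Calls for one marker as a Series indexed by line id."""
        j = self.gmap.marker_index(marker)
        return pd.Series(self.calls[:, j], index=self.line_ids, name=marker)


# ---------------------------------------------------------------------------
# .geno dialect
# ---------------------------------------------------------------------------


def read_geno(path: str | Path) -> tuple[GeneticMap, GenotypeMatrix]:
    """Parse a GeneNetwork-style ``.geno`` file.

    Lines beginning ``@`` are metadata (e.g. ``@mat B``), lines beginning
    ``#`` are comments.  The header row is ``Chr  Locus  cM  Mb  <line>...``
    and each data row holds one marker with codes B/D/H/U per line.
    """
    path = Path(path)
    header: list[str] | None = None
    rows: list[dict] = []
    calls: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("@"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields[:4] != ["Chr", "Locus", "cM", "Mb"]:
                    raise ParseError(
                        f"{path}:{lineno}: header must start 'Chr\\tLocus\\tcM\\tMb', "
                        f"got {fields[:4]}"
                    )
                header = fields
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            chrom, locus, cm, mb = fields[:4]
            try:
                cm_f, mb_f = float(cm), float(mb)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric cM/Mb {cm!r}/{mb!r}") from None
            row_calls = []
            for col, code in zip(header[4:], fields[4:]):
                if code not in _GENO_CODES:
                    raise ParseError(
                        f"{path}:{lineno}: unknown genotype code {code!r} for line {col}"
                    )
                row_calls.append(_GENO_CODES[code])
            rows.append({"marker": locus, "chromosome": chrom, "cM": cm_f, "Mb": mb_f})
            calls.append(row_calls)
    if header is None or not rows:
        raise ParseError(f"{path}: no marker rows found")
    map_tbl = pd.DataFrame(rows)
    # monotone-cM check in file order, per chromosome, before canonical sort
    for chrom, grp in map_tbl.groupby("chromosome", sort=False):
        cms = grp["cM"].to_numpy()
        if (np.diff(cms) < 0).any():
            raise ParseError(f"{path}: cM not non-decreasing on chromosome {chrom}")
    gmap = GeneticMap(map_tbl)
    # reorder call columns to the canonical marker order
    order = [map_tbl.index[map_tbl["marker"] == m][0] for m in gmap.table["marker"]]
    mat = np.asarray(calls, dtype=float)[order, :].T  # -> lines x markers
    G = GenotypeMatrix(line_ids=header[4:], calls=mat, gmap=gmap)
    return gmap, G


def write_geno(gmap: GeneticMap, G: GenotypeMatrix, path: str | Path) -> Path:
    """Write map + calls in the ``.geno`` dialect (inverse of :func:`read_geno`)."""
    if G.n_lines == 0:
        raise ValueError("cannot write a panel with 0 lines")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("@type riset\n@mat B\n@pat D\n@het H\n@unk U\n")
        fh.write("\t".join(["Chr", "Locus", "cM", "Mb", *G.line_ids]) + "\n")
        for j, row in gmap.table.iterrows():
            codes = [
                "U" if math.isnan(c) else _CODE_FOR_CALL[c] for c in G.calls[:, j]
            ]
            # repr() is the shortest lossless float form, keeping round-trips exact
            fh.write(
                f"{row['chromosome']}\t{row['marker']}\t{float(row['cM'])!r}\t{float(row['Mb'])!r}\t"
                + "\t".join(codes)
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# family phenotype table
# ---------------------------------------------------------------------------


@dataclass
class FamilyTable:
    """One row per family x day x role x trait, with litter covariates.

    ``line_id`` is the BXD line fostered into the family, for every role:
    B6 sibling and mother rows are attributed to the BXD half-litter they
    interacted with, which is what makes indirect-effect mapping possible.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(PHENO_COLUMNS) - set(df.columns)
        if missing:
            raise ParseError(f"phenotype table missing columns: {sorted(missing)}")
        problems: list[str] = []
        bad_day = ~df["day"].isin(DAYS)
        if bad_day.any():
            problems.append(f"invalid day at rows {df.index[bad_day].tolist()[:10]}")
        bad_role = ~df["role"].isin(ROLES)
        if bad_role.any():
            problems.append(f"invalid role at rows {df.index[bad_role].tolist()[:10]}")
        ok_role = ~bad_role
        pair_ok = pd.Series(False, index=df.index)
        for role, traits in TRAITS_BY_ROLE.items():
            pair_ok |= (df["role"] == role) & df["trait"].isin(traits)
        bad_pair = ok_role & ~pair_ok
        if bad_pair.any():
            problems.append(
                f"invalid role/trait combination at rows {df.index[bad_pair].tolist()[:10]}"
            )
        key = ["family_id", "day", "role", "trait"]
        dup = df.duplicated(subset=key)
        if dup.any():
            problems.append(f"duplicate (family_id, day, role, trait) at rows {df.index[dup].tolist()[:10]}")
        if problems:
            raise ParseError("invalid family table: " + "; ".join(problems))
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def rows_for(self, trait: str, role: str, day: int) -> pd.DataFrame:
        d = self.data
        return d[(d["trait"] == trait) & (d["role"] == role) & (d["day"] == day)]

    def missing_covariate_rows(self) -> pd.DataFrame:
        cont = [c for c in COVARIATES if c != "batch"]
        mask = self.data[cont].isna().any(axis=1) | self.data["batch"].isna()
        return self.data[mask]


def read_pheno(path: str | Path) -> FamilyTable:
    """Read and validate the family phenotype CSV."""
    df = pd.read_csv(path)
    try:
        return FamilyTable(df)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_pheno(tbl: FamilyTable, path: str | Path) -> Path:
    path = Path(path)
    tbl.data.to_csv(path, index=False, columns=list(PHENO_COLUMNS))
    return path


# ---------------------------------------------------------------------------
# locus report table
# ---------------------------------------------------------------------------

LOCUS_COLUMNS = (
    "locus",
    "phenotype",
    "effect_class",
    "day",
    "peak_Mb",
    "CI_Mb_low",
    "CI_Mb_high",
    "max_LRS",
    "max_LOD",
    "genomewide_p",
    "p_is_protected",
    "allele_increasing",
    "R2",
)


def _report_rows(reports: Iterable) -> list[dict]:
    rows = []
    for rep in reports:
        members = sorted(
            rep.members, key=lambda m: 0 if m.effect_class == "direct" else 1
        )
        for m in members:
            rows.append(
                {
                    "locus": rep.name,
                    "phenotype": f"{m.role}:{m.trait}",
                    "effect_class": m.effect_class,
                    "day": m.day,
                    "peak_Mb": m.peak_Mb,
                    "CI_Mb_low": m.ci_Mb[0],
                    "CI_Mb_high": m.ci_Mb[1],
                    "max_LRS": m.max_lrs,
                    "max_LOD": m.max_lod,
                    "genomewide_p": m.genomewide_p,
                    "p_is_protected": bool(m.p_is_protected),
                    "allele_increasing": m.allele_increasing,
                    "R2": m.r2,
                }
            )
    return rows


def write_locus_table(reports: Sequence, path: str | Path) -> tuple[Path, Path]:
    """Write locus reports as TSV and JSON; direct-effect rows come first.

    ``path`` names the TSV; the JSON sibling gets the same stem with a
    ``.json`` suffix. Returns both paths.
    """
    tsv_path = Path(path)
    json_path = tsv_path.with_suffix(".json")
    rows = _report_rows(reports)
    df = pd.DataFrame(rows, columns=list(LOCUS_COLUMNS))
    df.to_csv(tsv_path, sep="\t", index=False)
    json_path.write_text(json.dumps(rows, indent=2, default=float) + "\n")
    return tsv_path, json_path


def read_locus_json(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())
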