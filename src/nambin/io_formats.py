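"""Readers and writers for the tables the bin-map pipeline touches.

Dialects
--------
* **HapMap-like genotypes** — tab table with columns ``rs#``, ``alleles``
  (``A/B``), ``chrom``, ``pos`` followed by one column per line.  Homozygous
  calls are written as the single allele base, heterozygotes as the IUPAC
  ambiguity code of the two alleles (``X/Y`` also accepted on read), missing
  as ``NA`` (``N`` and ``./.`` accepted on read).
* **Minimal VCF v4.2** — ``GT``-only records, read through :mod:`pysam`.
  ``0/0`` → A, ``1/1`` → B, ``0/1``/``1/0`` → H, ``./.`` → missing.
* **Bin maps** — BED-like tab table (``chrom  start  end  bin_id`` with
  0-based half-open coordinates on disk) followed by one genotype column per
  line (``0``/``2``/``NA``).
* **CSV** for families (line, family), phenotypes (line, env, rep, value) and
  genetic maps (marker, chrom, pos, cM, distorted, framework).

Internally all coordinates are 1-based inclusive bp (maize AGP convention);
interval exports convert to BED 0-based half-open exactly (start-1, end).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# four-state call alphabet
CALL_A = 0   # homozygous for allele A
CALL_B = 1   # homozygous for allele B
CALL_H = 2   # heterozygous
CALL_NA = -1  # missing

_IUPAC_HET = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_MISSING_TOKENS = {"NA", "N", "./.", ".", "NN"}


class FormatError(ValueError):
    """Raised on malformed or inconsistent input tables."""


@dataclass
class GenotypeMatrix:
    """RILs x SNP sites with four-state calls.

    Attributes
    ----------
    lines : list of str
        Line (taxon) identifiers, one per matrix row.
    family_of : dict
        Maps every line to exactly one family identifier.
    sites : pandas.DataFrame
        Columns ``chrom``, ``pos`` (1-based bp), ``allele_a``, ``allele_b``;
        one row per matrix column, positions strictly increasing within a
        chromosome.
    calls : numpy.ndarray of int8, shape (n_lines, n_sites)
        Codes ``CALL_A``/``CALL_B``/``CALL_H``/``CALL_NA``.
    """

    lines: list
    family_of: dict
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.sites)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.sites)} sites"
            )
        if len(set(self.lines)) != len(self.lines):
            raise FormatError("duplicate line identifiers")
        missing_fam = [l for l in self.lines if l not in self.family_of]
        if missing_fam:
            raise FormatError(f"lines without family assignment: {missing_fam[:5]}")
        bad = ~np.isin(self.calls, [CALL_A, CALL_B, CALL_H, CALL_NA])
        if bad.any():
            raise FormatError("call codes outside the four-state alphabet")
        self._check_positions()

    def _check_positions(self):
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if (np.diff(pos) <= 0).any():
                j = int(np.flatnonzero(np.diff(pos) <= 0)[0])
                raise FormatError(
                    f"positions not strictly increasing on {chrom} near bp {pos[j]}"
                )

    @property
    def n_lines(self):
        return len(self.lines)

    @property
    def n_sites(self):
        return len(self.sites)

    def families(self):
        """Family ids in order of first appearance among lines."""
        seen = []
        for l in self.lines:
            f = self.family_of[l]
            if f not in seen:
                seen.append(f)
        return seen

    def subset_lines(self, keep):
        keep = list(keep)
        idx = [self.lines.index(l) for l in keep]
        return GenotypeMatrix(
            lines=keep,
            family_of={l: self.family_of[l] for l in keep},
            sites=self.sites.copy(),
            calls=self.calls[idx],
        )

    def subset_sites(self, mask):
        mask = np.asarray(mask)
        return GenotypeMatrix(
            lines=list(self.lines),
            family_of=dict(self.family_of),
            sites=self.sites.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask],
        )

    def family_matrix(self, family):
        keep = [l for l in self.lines if self.family_of[l] == family]
        return self.subset_lines(keep)

    def __eq__(self, other):
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.lines == other.lines
            and self.family_of == other.family_of
            and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PhenotypeTable:
    """Multi-environment trial records: (line, env, rep, value)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["line", "env", "rep", "value"]))

    def __post_init__(self):
        required = ["line", "env", "rep", "value"]
        if list(self.df.columns[:4]) != required:
            raise FormatError(f"phenotype table needs columns {required}")
        if self.df.duplicated(["line", "env", "rep"]).any():
            raise FormatError("duplicate (line, env, rep) keys")
        vals = self.df["value"].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise FormatError("non-finite trait values")

    def __eq__(self, other):
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------

def _decode_call(token, a, b, site_name):
    token = token.strip()
    if token in _MISSING_TOKENS:
        return CALL_NA
    if token == a:
        return CALL_A
    if token == b:
        return CALL_B
    if "/" in token:
        pair = frozenset(token.split("/"))
        if pair == frozenset((a, b)):
            return CALL_H
    if token == _IUPAC_HET.get(frozenset((a, b))):
        return CALL_H
    if token == a + a:
        return CALL_A
    if token == b + b:
        return CALL_B
    raise FormatError(f"unknown allele symbol {token!r} at site {site_name}")


def _encode_call(code, a, b):
    if code == CALL_A:
        return a
    if code == CALL_B:
        return b
    if code == CALL_H:
        return _IUPAC_HET.get(frozenset((a, b)), f"{a}/{b}")
    return "NA"


def read_genotypes(path, format="hapmap", families=None):
    """Read a genotype matrix.

    Parameters
    ----------
    path : path-like
    format : {"hapmap", "vcf"}
    families : dict or path-like, optional
        line -> family mapping, or a CSV with columns line,family.  Lines not
        covered default to family ``"fam0"``.
    """
    fam = _load_families(families)
    if format == "hapmap":
        return _read_hapmap(path, fam)
    if format == "vcf":
        return _read_vcf(path, fam)
    raise ValueError(f"unknown genotype format {format!r}")


def _load_families(families):
    if families is None:
        return {}
    if isinstance(families, dict):
        return dict(families)
    df = pd.read_csv(families)
    return dict(zip(df["line"].astype(str), df["family"].astype(str)))


def _finalize(lines, fam, sites, calls):
    sites = pd.DataFrame(sites, columns=["chrom", "pos", "allele_a", "allele_b"])
    dup = sites.duplicated(["chrom", "pos"])
    if dup.any():
        row = sites.loc[dup].iloc[0]
        raise FormatError(f"duplicate position {row['chrom']}:{row['pos']}")
    family_of = {l: fam.get(l, "fam0") for l in lines}
    return GenotypeMatrix(lines=lines, family_of=family_of, sites=sites,
                          calls=np.asarray(calls, dtype=np.int8).T)


def _read_hapmap(path, fam):
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["rs#", "alleles", "chrom", "pos"]:
            raise FormatError("expected HapMap-like header rs#/alleles/chrom/pos")
        lines = header[4:]
        sites, calls = [], []
        for ln in fh:
            fields = ln.rstrip("\n").split("\t")
            if len(fields) != 4 + len(lines):
                raise FormatError(f"ragged row at site {fields[0]}")
            name, alleles, chrom, pos = fields[:4]
            a, b = alleles.split("/")
            sites.append((chrom, int(pos), a, b))
            calls.append([_decode_call(t, a, b, name) for t in fields[4:]])
    return _finalize(lines, fam, sites, calls)


def _read_vcf(path, fam):
    import pysam

    vf = pysam.VariantFile(str(path))
    lines = list(vf.header.samples)
    sites, calls = [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise FormatError(f"site {rec.chrom}:{rec.pos} is not biallelic")
        a, b = rec.ref, rec.alts[0]
        sites.append((rec.chrom, rec.pos, a, b))
        row = []
        for s in lines:
            gt = rec.samples[s].get("GT")
            if gt is None or None in gt:
                row.append(CALL_NA)
            elif gt == (0, 0):
                row.append(CALL_A)
            elif gt == (1, 1):
                row.append(CALL_B)
            elif set(gt) == {0, 1}:
                row.append(CALL_H)
            else:
                raise FormatError(f"unknown genotype {gt} at {rec.chrom}:{rec.pos}")
        calls.append(row)
    vf.close()
    return _finalize(lines, fam, sites, calls)


def write_genotypes(matrix, path, format="hapmap"):
    """Write a genotype matrix (HapMap-like or minimal VCF v4.2)."""
    if format == "hapmap":
        _write_hapmap(matrix, path)
    elif format == "vcf":
        _write_vcf(matrix, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_hapmap(matrix, path):
    with open(path, "w") as fh:
        fh.write("\t".join(["rs#", "alleles", "chrom", "pos"] + list(matrix.lines)) + "\n")
        for j, site in matrix.sites.iterrows():
            a, b = site["allele_a"], site["allele_b"]
            toks = [_encode_call(int(c), a, b) for c in matrix.calls[:, j]]
            fh.write("\t".join(
                [f"s{j}", f"{a}/{b}", str(site["chrom"]), str(site["pos"])] + toks) + "\n")


def _write_vcf(matrix, path):
    gt_token = {CALL_A: "0/0", CALL_B: "1/1", CALL_H: "0/1", CALL_NA: "./."}
    chrom_len = matrix.sites.groupby("chrom", sort=False)["pos"].max()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, ln in chrom_len.items():
            fh.write(f"##contig=<ID={chrom},length={int(ln) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.lines) + "\n")
        for j, site in matrix.sites.iterrows():
            toks = [gt_token[int(c)] for c in matrix.calls[:, j]]
            fh.write("\t".join([str(site["chrom"]), str(site["pos"]), f"s{j}",
                                site["allele_a"], site["allele_b"], ".", ".", ".",
                                "GT"] + toks) + "\n")


def write_families(family_of, path):
    pd.DataFrame(
        {"line": list(family_of), "family": [family_of[l] for l in family_of]}
    ).to_csv(path, index=False)


def read_families(path):
    return _load_families(path)


# ---------------------------------------------------------------------------
# bin map
# ---------------------------------------------------------------------------

def write_bin_map(bin_map, path):
    """Write a bin map as a BED-like table plus the RIL x bin genotype matrix.

    On-disk coordinates are 0-based half-open; internal are 1-based inclusive.
    Overlapping or unsorted bins are a hard error.
    """
    bins = bin_map.bins
    for chrom, grp in bins.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] <= ends[:-1]).any():
            raise FormatError(f"overlapping or unsorted bins on {chrom}")
    with open(path, "w") as fh:
        fh.write("\t".join(["#chrom", "start", "end", "bin_id"] + list(bin_map.lines)) + "\n")
        for k in range(len(bins)):
            row = bins.iloc[k]
            toks = ["NA" if g == CALL_NA else str(int(g))
                    for g in bin_map.genotypes[:, k]]
            fh.write("\t".join([str(row["chrom"]), str(int(row["start"]) - 1),
                                str(int(row["end"])), f"bin{k:05d}"] + toks) + "\n")


def read_bin_map(path):
    from .bin_builder import BinMap

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["#chrom", "start", "end", "bin_id"]:
            raise FormatError("expected bin-map header #chrom/start/end/bin_id")
        lines = header[4:]
        recs, geno = [], []
        for ln in fh:
            fields = ln.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            recs.append((chrom, start + 1, end))
            geno.append([CALL_NA if t == "NA" else int(t) for t in fields[4:]])
    bins = pd.DataFrame(recs, columns=["chrom", "start", "end"])
    g = (np.asarray(geno, dtype=np.int8).T if geno
         else np.zeros((len(lines), 0), dtype=np.int8))
    return BinMap(bins=bins, lines=lines, genotypes=g)


# ---------------------------------------------------------------------------
# phenotypes, maps, truth
# ---------------------------------------------------------------------------

def write_phenotypes(table, path):
    table.df.to_csv(path, index=False)


def read_phenotypes(path):
    df = pd.read_csv(path)
    df["line"] = df["line"].astype(str)
    df["env"] = df["env"].astype(str)
    return PhenotypeTable(df=df)


def write_genetic_map(gmap, path):
    gmap.markers.to_csv(path, index=False)


def read_genetic_map(path):
    from .genetic_map import GeneticMap

    return GeneticMap(markers=pd.read_csv(path))


def write_truth(truth, path):
    """TruthSet -> JSON (segments, breakpoints, QTL) alongside the BED export."""
    payload = {
        "chrom_lengths": truth.chrom_lengths,
        "segments": {
            ril: [[c, int(s), int(e), int(g)] for (c, s, e, g) in segs]
            for ril, segs in truth.segments.items()
        },
        "qtl": truth.qtl,
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path):
    from .synthetic_data import TruthSet

    payload = json.loads(Path(path).read_text())
    return TruthSet(
        chrom_lengths={k: int(v) for k, v in payload["chrom_lengths"].items()},
        segments={
            ril: [(c, int(s), int(e), int(g)) for c, s, e, g in segs]
            for ril, segs in payload["segments"].items()
        },
        qtl=payload["qtl"],
    )
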