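"""Coverage-track normalization, gene-region binning and profile averaging.

This module builds the empirical side of the model comparison from per-base
coverage tracks (cleavage frequency or read depth):

* counts-per-million normalization (``cpm_normalize``) and background
  subtraction of the soluble-nuclease control (``background_subtract``);
* the fixed gene-region scheme — UAS −500..−151 and promoter −150..+25
  relative to the TSS, transcript +26 (TSS) to −76 (TES), terminator
  −75..+150 relative to the TES, all in transcription direction — giving
  constant region widths of 350 / 176 / 226 bp (``gene_regions``);
* per-region, length-normalized means (``region_means``) that assemble the
  empirical region vectors the kinetic model is fitted to;
* length-normalized metagene profiles (three segments × 100 bins) and
  oriented metasite profiles with sliding-window smoothing.

Coordinates are 0-based half-open internally; BED stays 0-based half-open
and GFF3 is converted to/from 1-based inclusive at the boundary.  The
relative offsets above are interpreted with offset 0 = the TSS (or TES) base
itself, so e.g. −150..+25 spans 176 bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import GeneClass
from .occupancy import RegionOccupancy

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack", "GeneModel", "RegionScheme", "Profile", "RegionError",
    "cpm_normalize", "background_subtract", "gene_regions", "region_means",
    "metagene_profile", "metasite_profile", "empirical_region_vector",
    "Site", "read_bedgraph", "read_genes_bed", "write_genes_bed",
    "read_genes_gff3", "write_genes_gff3", "read_sites_bed",
    "write_sites_bed", "MEDIAN_UTR5", "MEDIAN_UTR3",
]

VALID_UNITS = ("raw", "CPM", "CPMn", "delta")
#: Median yeast UTR lengths used as TSS/TES fallbacks when a gene's
#: annotation carries only the coding region.
MEDIAN_UTR5 = 47
MEDIAN_UTR3 = 118


class RegionError(ValueError):
    """A gene is too short (or too close to a contig edge) for the scheme."""


@dataclass
class CoverageTrack:
    """Per-base signal over named reference sequences."""

    data: dict  # chrom -> float ndarray
    units: str = "raw"

    def __post_init__(self):
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}")
        self.data = {c: np.asarray(v, dtype=float)
                     for c, v in self.data.items()}
        if self.units != "delta":
            for c, v in self.data.items():
                if (v < 0).any():
                    raise ValueError(f"negative values in non-delta track "
                                     f"({c})")

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def chrom_sizes(self) -> dict:
        return {c: len(v) for c, v in self.data.items()}

    # -- bedGraph I/O -----------------------------------------------------
    def to_bedgraph(self, path) -> None:
        """Write runs of constant nonzero signal as bedGraph intervals."""
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                v = self.data[chrom]
                if len(v) == 0:
                    continue
                breaks = np.flatnonzero(np.diff(v) != 0) + 1
                starts = np.concatenate([[0], breaks])
                ends = np.concatenate([breaks, [len(v)]])
                for s, e in zip(starts, ends):
                    if v[s] != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.10g}\n")


def read_bedgraph(path, chrom_sizes: dict, units: str = "raw"
                  ) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "start", "end", "value"])
    data = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    for chrom, start, end, value in df.itertuples(index=False):
        if chrom not in data:
            raise ValueError(f"bedGraph chrom {chrom!r} not in chrom_sizes")
        data[chrom][start:end] += value
    return CoverageTrack(data=data, units=units)


def cpm_normalize(track: CoverageTrack, units_out: str = "CPM"
                  ) -> CoverageTrack:
    """Scale a raw-count track so its genome-wide sum is 10⁶.

    ``units_out`` selects the label: "CPM" for read-depth tracks, "CPMn" for
    cleavage-frequency tracks.  Normalizing twice is a unit error.
    """
    if track.units != "raw":
        raise ValueError(f"track already normalized (units={track.units!r})")
    if units_out not in ("CPM", "CPMn"):
        raise ValueError("units_out must be 'CPM' or 'CPMn'")
    total = track.total
    if total <= 0:
        raise ValueError("cannot CPM-normalize a track with zero total")
    factor = 1e6 / total
    return CoverageTrack(data={c: v * factor for c, v in track.data.items()},
                         units=units_out)


def background_subtract(specific: CoverageTrack, control: CoverageTrack
                        ) -> CoverageTrack:
    """Elementwise specific − control (both CPM/CPMn); output may be signed."""
    if specific.units != control.units or specific.units not in ("CPM",
                                                                 "CPMn"):
        raise ValueError(f"unit mismatch: {specific.units!r} vs "
                         f"{control.units!r} (both must be CPM or CPMn)")
    if specific.chrom_sizes() != control.chrom_sizes():
        raise ValueError("tracks cover different references")
    data = {c: specific.data[c] - control.data[c] for c in specific.data}
    return CoverageTrack(data=data, units="delta")


# ---------------------------------------------------------------------------
# Gene models and regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene as TSS/TES coordinates (0-based positions of the first and
    last transcribed bases; for minus-strand genes ``tss > tes``)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    provenance: str = "annotated"  # or "utr_fallback"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: plus-strand gene needs "
                             "tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: minus-strand gene needs "
                             "tss > tes")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss) + 1

    @property
    def start(self) -> int:  # leftmost transcribed base (0-based)
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:    # half-open right end
        return max(self.tss, self.tes) + 1

    @classmethod
    def from_cds(cls, gene_id, chrom, strand, cds_start, cds_end,
                 utr5: int = MEDIAN_UTR5, utr3: int = MEDIAN_UTR3
                 ) -> "GeneModel":
        """Extend a coding interval by the median UTR lengths when no
        transcript-level TSS/TES annotation exists."""
        if strand == "+":
            return cls(gene_id, chrom, strand, cds_start - utr5,
                       cds_end - 1 + utr3, provenance="utr_fallback")
        return cls(gene_id, chrom, strand, cds_end - 1 + utr5,
                   cds_start - utr3, provenance="utr_fallback")


@dataclass(frozen=True)
class RegionScheme:
    """Relative region offsets (inclusive, transcription direction,
    offset 0 = the anchor base)."""

    uas: tuple = (-500, -151)         # relative to TSS
    promoter: tuple = (-150, 25)      # relative to TSS
    transcript_start: int = 26        # relative to TSS
    transcript_end: int = -76         # relative to TES
    terminator: tuple = (-75, 150)    # relative to TES


def _rel_interval(anchor: int, strand: str, a: int, b: int
                  ) -> tuple[int, int]:
    """Inclusive relative offsets (a <= b, in transcription direction) to an
    absolute 0-based half-open interval."""
    if strand == "+":
        return anchor + a, anchor + b + 1
    return anchor - b, anchor - a + 1


def gene_regions(gene: GeneModel, scheme: RegionScheme = RegionScheme()
                 ) -> dict[str, tuple[str, int, int]]:
    """The four strand-aware region intervals of a gene, 0-based half-open.

    Raises :class:`RegionError` when the transcript region would be empty
    (callers skip and log such genes).
    """
    regions = {
        "UAS": _rel_interval(gene.tss, gene.strand, *scheme.uas),
        "promoter": _rel_interval(gene.tss, gene.strand, *scheme.promoter),
    }
    if gene.strand == "+":
        tx = (gene.tss + scheme.transcript_start,
              gene.tes + scheme.transcript_end + 1)
    else:
        tx = (gene.tes - scheme.transcript_end,
              gene.tss - scheme.transcript_start + 1)
    if tx[1] <= tx[0]:
        raise RegionError(f"{gene.gene_id}: transcript region empty "
                          f"(gene length {gene.length} bp)")
    regions["transcript"] = tx
    regions["3'UTR"] = _rel_interval(gene.tes, gene.strand,
                                     *scheme.terminator)
    return {name: (gene.chrom, s, e) for name, (s, e) in regions.items()}


def region_means(track: CoverageTrack, regions: dict
                 ) -> dict[str, float]:
    """Mean signal per bp for each region; out-of-bounds regions are clipped
    (with a warning) and the mean uses the clipped width."""
    out = {}
    for name, (chrom, start, end) in regions.items():
        v = track.data[chrom]
        s, e = max(0, start), min(len(v), end)
        if (s, e) != (start, end):
            logger.warning("region %s [%d, %d) clipped to [%d, %d) on %s",
                           name, start, end, s, e, chrom)
        if e <= s:
            out[name] = 0.0
            continue
        out[name] = float(v[s:e].mean())
    return out


def empirical_region_vector(track: CoverageTrack, genes: list[GeneModel],
                            gene_class: GeneClass,
                            scheme: RegionScheme = RegionScheme(),
                            gene_counts: dict | None = None,
                            min_counts: float = 0.0) -> RegionOccupancy:
    """Average region means across genes into the empirical vector Eᵢ fed to
    the fitting stage.

    ``gene_counts``/``min_counts`` implement the optional minimum-expression
    filter (genes below the nascent-count threshold are excluded).
    """
    gene_class = GeneClass(gene_class)
    labels = (("UAS", "promoter", "transcript", "3'UTR")
              if gene_class is GeneClass.STM
              else ("promoter", "transcript", "3'UTR"))
    rows = []
    for gene in genes:
        if gene_counts is not None and \
                gene_counts.get(gene.gene_id, 0.0) < min_counts:
            continue
        try:
            regions = gene_regions(gene, scheme)
        except RegionError as err:
            logger.info("skipping gene: %s", err)
            continue
        means = region_means(track, regions)
        rows.append([means[lab] for lab in labels])
    if not rows:
        raise ValueError("no usable genes for the empirical vector")
    arr = np.array(rows)
    se = arr.std(axis=0, ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 \
        else np.zeros(arr.shape[1])
    return RegionOccupancy(gene_class=gene_class, values=arr.mean(axis=0),
                           se=se, units=track.units)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class Profile:
    """Position-indexed mean signal with the number of contributing
    genes/sites."""

    positions: np.ndarray
    values: np.ndarray
    n: int
    kind: str = "metagene"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions,
                             "value": self.values})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _bin_means(v: np.ndarray, nbins: int) -> np.ndarray:
    """Means over nbins contiguous chunks (edges by linspace floor)."""
    edges = np.floor(np.linspace(0, len(v), nbins + 1)).astype(int)
    sums = np.add.reduceat(v, edges[:-1])
    widths = np.diff(edges)
    return sums / widths


def metagene_profile(tracks: list[CoverageTrack], genes: list[GeneModel],
                     flank: int = 1000, nbins: int = 100) -> Profile:
    """Length-normalized average profile over genes.

    Order of operations: average the replicate tracks per base pair, cut each
    gene into three transcription-oriented segments (upstream flank,
    TSS→TES, downstream flank), bin each segment into ``nbins`` bins, then
    average across genes.  Genes with a body shorter than ``nbins`` bp — one
    bp per bin — or flanks off the contig are skipped with a log entry.
    """
    if not tracks or not genes:
        raise ValueError("need at least one track and one gene")
    sizes = tracks[0].chrom_sizes()
    if any(t.chrom_sizes() != sizes for t in tracks[1:]):
        raise ValueError("replicate tracks cover different references")
    avg = {c: np.mean([t.data[c] for t in tracks], axis=0) for c in sizes}
    profiles = []
    for gene in genes:
        v = avg[gene.chrom]
        if gene.length < nbins:
            logger.info("skipping %s: body %d bp < %d bins", gene.gene_id,
                        gene.length, nbins)
            continue
        if gene.start - flank < 0 or gene.end + flank > len(v):
            logger.info("skipping %s: flank outside contig", gene.gene_id)
            continue
        body = v[gene.start:gene.end]
        up = v[gene.start - flank:gene.start]
        down = v[gene.end:gene.end + flank]
        if gene.strand == "-":
            body, up, down = body[::-1], down[::-1], up[::-1]
        profiles.append(np.concatenate([_bin_means(up, nbins),
                                        _bin_means(body, nbins),
                                        _bin_means(down, nbins)]))
    if not profiles:
        raise ValueError("no usable genes for the metagene profile")
    values = np.mean(profiles, axis=0)
    positions = np.arange(3 * nbins, dtype=float)
    return Profile(positions=positions, values=values, n=len(profiles),
                   kind="metagene")


@dataclass(frozen=True)
class Site:
    """An oriented genomic point (e.g. a TATA box)."""

    chrom: str
    pos: int
    strand: str = "+"
    name: str = "."


def metasite_profile(track: CoverageTrack, sites: list[Site],
                     flank: int = 250, window: int = 10, step: int = 5
                     ) -> Profile:
    """Average signal around oriented sites ± ``flank`` bp, then smooth with
    a sliding-window mean.

    Minus-strand sites contribute their window reversed, so profiles are in
    site orientation.  Only windows lying fully inside the flank are
    emitted (no partial windows at the edges); the reported position of each
    smoothed point is the center of its window relative to the site.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    width = 2 * flank + 1
    rows = []
    for site in sites:
        v = track.data[site.chrom]
        lo, hi = site.pos - flank, site.pos + flank + 1
        if lo < 0 or hi > len(v):
            logger.info("skipping site %s:%d (within %d bp of contig edge)",
                        site.chrom, site.pos, flank)
            continue
        seg = v[lo:hi]
        rows.append(seg[::-1] if site.strand == "-" else seg)
    if not rows:
        raise ValueError("no usable sites for the metasite profile")
    mean = np.mean(rows, axis=0)
    n_out = (width - window) // step + 1
    values = np.array([mean[j * step: j * step + window].mean()
                       for j in range(n_out)])
    positions = -flank + np.arange(n_out) * step + (window - 1) / 2.0
    return Profile(positions=positions, values=values, n=len(rows),
                   kind="metasite")


# ---------------------------------------------------------------------------
# Annotation I/O (BED 0-based half-open; GFF3 1-based inclusive)
# ---------------------------------------------------------------------------

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_genes_bed(genes: list[GeneModel], path) -> None:
    rows = [(g.chrom, g.start, g.end, g.gene_id,
             0 if g.provenance == "annotated" else 1, g.strand)
            for g in genes]
    pd.DataFrame(rows, columns=_BED_COLS).to_csv(
        path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", names=_BED_COLS, comment="#")
    genes = []
    for r in df.itertuples(index=False):
        tss, tes = (r.start, r.end - 1) if r.strand == "+" \
            else (r.end - 1, r.start)
        genes.append(GeneModel(
            gene_id=str(r.name), chrom=str(r.chrom), strand=r.strand,
            tss=tss, tes=tes,
            provenance="annotated" if r.score == 0 else "utr_fallback"))
    return genes


def write_genes_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tpolkin\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};"
                     f"provenance={g.provenance}\n")


def read_genes_gff3(path) -> list[GeneModel]:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _, ftype, start, end, _, strand, _, attrs = \
            line.split("\t")
        if ftype != "gene":
            continue
        ad = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        start0, end0 = int(start) - 1, int(end)
        tss, tes = (start0, end0 - 1) if strand == "+" else (end0 - 1, start0)
        genes.append(GeneModel(gene_id=ad.get("ID", "."), chrom=chrom,
                               strand=strand, tss=tss, tes=tes,
                               provenance=ad.get("provenance", "annotated")))
    return genes


def write_sites_bed(sites: list[Site], path) -> None:
    rows = [(s.chrom, s.pos, s.pos + 1, s.name, 0, s.strand) for s in sites]
    pd.DataFrame(rows, columns=_BED_COLS).to_csv(
        path, sep="\t", header=False, index=False)


def read_sites_bed(path) -> list[Site]:
    df = pd.read_csv(path, sep="\t", names=_BED_COLS, comment="#")
    return [Site(chrom=str(r.chrom), pos=int(r.start), strand=r.strand,
                 name=str(r.name)) for r in df.itertuples(index=False)]
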