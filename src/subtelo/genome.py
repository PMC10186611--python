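"""Genome model: chromosomes, centromeres, arms and telomere distances.

Telomeres are taken to sit at both extremities of every assembled
chromosome (coordinate 0 and coordinate L).  Each chromosome is split by
its centromere into a p arm (telomere at 0) and a q arm (telomere at L),
and every gene is assigned a distance to its closest telomere together
with the arm that telomere belongs to.  All internal coordinates are
0-based half-open; GTF/GFF3 input (1-based inclusive) is converted on
read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger("subtelo")

Anchor = Literal["nearest_edge", "start", "midpoint", "tss"]

#: biotypes retained by default: protein-coding genes plus every
#: pseudogene flavour (processed_pseudogene, unprocessed_pseudogene, ...)
DEFAULT_BIOTYPE_FILTER = ("protein_coding", "*pseudogene")


class GenomeModelError(ValueError):
    """Raised for invalid assemblies, annotations or coordinates."""


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome lengths plus centromere intervals defining arms.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs, lengths in base pairs.
    centromeres
        Map chromosome name -> ``(start, end)`` half-open interval.
        A zero-width interval marks a chromosome whose centromere was
        unknown and defaulted to the midpoint.
    excluded_arms
        Arm identifiers (``"chr13p"`` style) removed from window-based
        analyses, e.g. acrocentric short arms.
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: dict[str, tuple[int, int]]
    excluded_arms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise GenomeModelError("duplicate chromosome name in assembly")
        for name, length in self.chromosomes:
            if length <= 0:
                raise GenomeModelError(f"chromosome {name} has length {length} <= 0")
        lengths = dict(self.chromosomes)
        for name, (start, end) in self.centromeres.items():
            if name not in lengths:
                raise GenomeModelError(f"centromere on unknown chromosome {name}")
            if not (0 <= start <= end <= lengths[name]):
                raise GenomeModelError(
                    f"centromere ({start}, {end}) outside chromosome {name} "
                    f"of length {lengths[name]}"
                )
        valid = set(self.arms())
        unknown = set(self.excluded_arms) - valid
        if unknown:
            raise GenomeModelError(f"excluded arms not in assembly: {sorted(unknown)}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def arms(self) -> list[str]:
        """All arm identifiers, ``{chrom}p`` and ``{chrom}q``, in order."""
        return [name + arm for name, _ in self.chromosomes for arm in ("p", "q")]

    def centromere(self, chrom: str) -> tuple[int, int]:
        return self.centromeres[chrom]


def load_assembly(
    chrom_sizes_path: str | Path,
    centromere_path: str | Path | None = None,
    excluded_arms: Iterable[str] = (),
) -> GenomeAssembly:
    """Build a :class:`GenomeAssembly` from a chrom.sizes file and a
    centromere BED.

    Chromosomes missing from the centromere file get a zero-width
    centromere at the midpoint (logged) so arm assignment still works.
    """
    sizes = pd.read_csv(
        chrom_sizes_path, sep="\t", header=None, usecols=[0, 1],
        names=["chrom", "length"], dtype={"chrom": str},
    )
    if sizes["chrom"].duplicated().any():
        dupes = sizes.loc[sizes["chrom"].duplicated(), "chrom"].tolist()
        raise GenomeModelError(f"duplicate chromosome name(s) in chrom.sizes: {dupes}")
    chromosomes = tuple(zip(sizes["chrom"], sizes["length"].astype(int)))
    lengths = dict(chromosomes)

    centromeres: dict[str, tuple[int, int]] = {}
    if centromere_path is not None:
        bed = pd.read_csv(
            centromere_path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], dtype={"chrom": str},
        )
        for row in bed.itertuples(index=False):
            if row.chrom not in lengths:
                raise GenomeModelError(f"centromere on unknown chromosome {row.chrom}")
            centromeres[row.chrom] = (int(row.start), int(row.end))
    missing = [name for name in lengths if name not in centromeres]
    for name in missing:
        mid = lengths[name] // 2
        centromeres[name] = (mid, mid)
    if missing:
        logger.warning(
            "no centromere record for %d chromosome(s) (%s...): using zero-width "
            "midpoint centromeres", len(missing), missing[0],
        )
    return GenomeAssembly(chromosomes, centromeres, frozenset(excluded_arms))


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One gene, 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeModelError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise GenomeModelError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def tss(self) -> int:
        # 5' end; last covered base for minus-strand genes
        return self.end - 1 if self.strand == "-" else self.start


GeneTable = list


def _biotype_ok(biotype: str, patterns: Sequence[str]) -> bool:
    for pat in patterns:
        if pat.startswith("*"):
            if biotype.endswith(pat[1:]):
                return True
        elif biotype == pat:
            return True
    return False


def _genes_from_gxf(path: str | Path) -> Iterable[tuple[str, str, int, int, str, str]]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        gene_id = (attrs.get("gene_id") or attrs.get("ID") or [feat.id])[0]
        biotype = (
            attrs.get("gene_biotype") or attrs.get("gene_type")
            or attrs.get("biotype") or ["protein_coding"]
        )[0]
        # GTF/GFF3 are 1-based inclusive -> 0-based half-open
        yield gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand or ".", biotype


def _genes_from_bed(path: str | Path) -> Iterable[tuple[str, str, int, int, str, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise GenomeModelError(
                    f"{path}: line {lineno}: BED gene record needs >= 4 columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise GenomeModelError(f"{path}: line {lineno}: {exc}") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            biotype = fields[6] if len(fields) > 6 else "protein_coding"
            yield fields[3], fields[0], start, end, strand, biotype


def load_gene_annotation(
    path: str | Path,
    fmt: Literal["gtf", "gff3", "bed"] = "gtf",
    biotype_filter: Sequence[str] | None = DEFAULT_BIOTYPE_FILTER,
    assembly: GenomeAssembly | None = None,
) -> list[GeneRecord]:
    """Read gene records from GTF/GFF3/BED, filtered to the requested
    biotypes (default protein-coding + all pseudogene classes).

    Genes on chromosomes absent from ``assembly`` are skipped with a
    logged count; an empty post-filter table is an error.
    """
    if fmt in ("gtf", "gff3"):
        raw = _genes_from_gxf(path)
    elif fmt == "bed":
        raw = _genes_from_bed(path)
    else:
        raise GenomeModelError(f"unknown annotation format {fmt!r}")

    lengths = assembly.lengths if assembly is not None else None
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    n_offchrom = 0
    for gene_id, chrom, start, end, strand, biotype in raw:
        if biotype_filter is not None and not _biotype_ok(biotype, biotype_filter):
            continue
        if lengths is not None:
            if chrom not in lengths:
                n_offchrom += 1
                continue
            if end > lengths[chrom]:
                raise GenomeModelError(
                    f"gene {gene_id} extends past chromosome {chrom} "
                    f"({end} > {lengths[chrom]})"
                )
        if gene_id in seen:
            raise GenomeModelError(f"duplicate gene_id {gene_id} in annotation")
        seen.add(gene_id)
        genes.append(GeneRecord(gene_id, chrom, start, end, strand, biotype))
    if n_offchrom:
        logger.info("skipped %d gene(s) on chromosomes absent from assembly", n_offchrom)
    if not genes:
        raise GenomeModelError(f"no genes left after biotype filtering of {path}")
    return genes


def write_gene_bed(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{g.biotype}\n")


# ---------------------------------------------------------------------------
# telomere distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TelomereDistance:
    gene_id: str
    distance: int
    arm: str
    anchor: Anchor


def _anchor_coords(gene: GeneRecord, anchor: Anchor) -> tuple[int, int]:
    """(d_p, d_q): distances of the anchor to the 0-side and L-side ends,
    before subtracting; returns the p-side coordinate and the coordinate
    measured toward q as (a_p, a_q_offset is L - value handled by caller).
    """
    if anchor == "nearest_edge":
        return gene.start, gene.end
    if anchor == "start":
        a = gene.start
    elif anchor == "midpoint":
        a = gene.midpoint
    elif anchor == "tss":
        a = gene.tss
    else:
        raise GenomeModelError(f"unknown anchor {anchor!r}")
    return a, a


def telomere_distance(
    gene: GeneRecord, assembly: GenomeAssembly, anchor: Anchor = "nearest_edge"
) -> TelomereDistance:
    """Distance of one gene to its closest telomere and the owning arm.

    With the default ``nearest_edge`` anchor, the p-side distance is the
    gene start and the q-side distance is ``L - end``; single-point
    anchors use one coordinate for both sides.  Equidistant genes are
    assigned to the p arm.
    """
    length = assembly.lengths.get(gene.chrom)
    if length is None:
        raise GenomeModelError(f"gene {gene.gene_id} on unknown chromosome {gene.chrom}")
    if gene.end > length:
        raise GenomeModelError(
            f"gene {gene.gene_id} extends past chromosome {gene.chrom}"
        )
    a_p, a_q = _anchor_coords(gene, anchor)
    d_p, d_q = a_p, length - a_q
    if d_p <= d_q:
        return TelomereDistance(gene.gene_id, d_p, gene.chrom + "p", anchor)
    return TelomereDistance(gene.gene_id, d_q, gene.chrom + "q", anchor)


def distance_table(
    genes: Sequence[GeneRecord],
    assembly: GenomeAssembly,
    anchor: Anchor = "nearest_edge",
) -> pd.DataFrame:
    """Per-gene telomere distances as a DataFrame with columns
    ``gene_id, chrom, arm, distance_bp, anchor``."""
    rows = []
    for g in genes:
        td = telomere_distance(g, assembly, anchor)
        rows.append((g.gene_id, g.chrom, td.arm, td.distance, anchor))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "arm", "distance_bp", "anchor"])


# ---------------------------------------------------------------------------
# subtelomere windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubtelomereWindow:
    """Terminal window of one chromosome arm.

    ``start``/``end`` are chromosome coordinates; ``effective_width`` is
    the window extent measured from its telomere, which is what distance
    based membership tests compare against.
    """

    arm: str
    chrom: str
    start: int
    end: int
    width: int = 2_000_000

    @property
    def effective_width(self) -> int:
        return self.end - self.start


def define_subtelomere_windows(
    assembly: GenomeAssembly,
    width: int = 2_000_000,
    clip_at_centromere: bool = False,
) -> list[SubtelomereWindow]:
    """Terminal ``width`` bp windows of every non-excluded arm.

    The p window is ``[0, width)`` and the q window ``[L - width, L)``,
    truncated at the chromosome (with a warning) and, when
    ``clip_at_centromere`` is set, at the centromere boundary.
    """
    if width <= 0:
        raise GenomeModelError("window width must be > 0")
    windows: list[SubtelomereWindow] = []
    for chrom, length in assembly.chromosomes:
        if width >= length:
            logger.warning(
                "window width %d >= chromosome %s length %d: truncating",
                width, chrom, length,
            )
        cen_start, cen_end = assembly.centromeres[chrom]
        for arm_letter in ("p", "q"):
            arm = chrom + arm_letter
            if arm in assembly.excluded_arms:
                continue
            if arm_letter == "p":
                start, end = 0, min(width, length)
                if clip_at_centromere:
                    end = min(end, cen_start)
            else:
                start, end = max(length - width, 0), length
                if clip_at_centromere:
                    start = max(start, cen_end)
            if end <= start:
                logger.warning("arm %s has an empty subtelomere window: skipped", arm)
                continue
            windows.append(SubtelomereWindow(arm, chrom, start, end, width))
    return windows


def genes_in_window(
    distances: pd.DataFrame, window: SubtelomereWindow
) -> pd.Series:
    """Boolean mask over a distance table: anchor within the window."""
    return (distances["arm"] == window.arm) & (
        distances["distance_bp"] < window.effective_width
    )
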