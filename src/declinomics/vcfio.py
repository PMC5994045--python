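"""File-format I/O: VCF (via pysam), FASTA (via Biopython), GeoJSON.

Only biallelic SNV records with a GT FORMAT field are loaded from VCF;
anything else (multi-allelic, indels, missing GT) is skipped and counted.
``write_vcf`` followed by ``read_vcf`` is the identity on supported records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from Bio import SeqIO
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .variants import MISSING, VariantTable

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """Raised on VCF records or headers that cannot be interpreted."""


@dataclass
class VcfReadResult:
    table: VariantTable
    n_skipped: int


def read_vcf(path, return_skipped: bool = False):
    """Load biallelic SNVs with GT calls from a VCF file.

    Unsupported records (multi-allelic, non-SNV alleles, absent GT) are
    skipped; the count is logged and available with ``return_skipped=True``.
    """
    path = str(path)
    contigs, pos, ref, alt, rows = [], [], [], [], []
    n_skipped = 0
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    if "GT" not in vcf.header.formats:
        raise VcfFormatError(f"{path}: no GT FORMAT declared in header")
    for rec in vcf:
        alts = rec.alts or ()
        if (
            len(alts) != 1
            or rec.ref is None
            or len(rec.ref) != 1
            or len(alts[0]) != 1
            or rec.ref.upper() not in _BASES
            or alts[0].upper() not in _BASES
        ):
            n_skipped += 1
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for j, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                row[j] = MISSING
            else:
                row[j] = sum(1 for a in gt if a == 1)
        contigs.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref.upper())
        alt.append(alts[0].upper())
        rows.append(row)
    vcf.close()
    if n_skipped:
        logger.info("%s: skipped %d unsupported records", path, n_skipped)
    table = VariantTable(
        contigs=np.array(contigs, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=np.array(rows, dtype=np.int8).reshape(len(rows), len(samples)),
        samples=samples,
    )
    if return_skipped:
        return VcfReadResult(table, n_skipped)
    return table


def write_vcf(table: VariantTable, path) -> None:
    """Write a VariantTable as uncompressed VCF v4.2 with GT-only FORMAT."""
    path = str(path)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lengths: dict = {}
    for c, p in zip(table.contigs, table.pos):
        lengths[c] = max(lengths.get(c, 0), int(p))
    for c, length in lengths.items():
        header.contigs.add(str(c), length=length + 1)
    for s in table.samples:
        header.add_sample(s)
    out = pysam.VariantFile(path, "w", header=header)
    for i in range(table.n_sites):
        rec = out.new_record(
            contig=str(table.contigs[i]),
            start=int(table.pos[i]) - 1,
            stop=int(table.pos[i]),
            alleles=(str(table.ref[i]), str(table.alt[i])),
        )
        for j, s in enumerate(table.samples):
            g = int(table.genotypes[i, j])
            if g == MISSING:
                rec.samples[s]["GT"] = (None, None)
            else:
                rec.samples[s]["GT"] = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g]
        out.write(rec)
    out.close()


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_geojson(
    path,
    points: Sequence[tuple[float, float]] | None = None,
    labels: Sequence[str] | None = None,
    polygons: Sequence[BaseGeometry] | None = None,
) -> None:
    """Write occurrence points and/or habitat polygons as a FeatureCollection."""
    features = []
    for i, pt in enumerate(points or []):
        props = {"label": labels[i]} if labels else {}
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(pt)},
                "properties": props,
            }
        )
    for geom in polygons or []:
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": {}}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_geojson(path) -> tuple[list[tuple[float, float]], list[str], list[BaseGeometry]]:
    """Read back points (with labels) and polygons from a FeatureCollection."""
    data = json.loads(Path(path).read_text())
    points: list[tuple[float, float]] = []
    labels: list[str] = []
    polys: list[BaseGeometry] = []
    for feat in data.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") == "Point":
            x, y = geom["coordinates"][:2]
            points.append((float(x), float(y)))
            labels.append(feat.get("properties", {}).get("label", ""))
        else:
            polys.append(shape(geom))
    return points, labels, polys
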