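"""File formats: nucleus tables (TSV), surface grids (TSV/TIFF), BED6,
GFF3 gene models, and JSON reports/ground truth.

Conventions: lengths in µm, genomic coordinates in bp (internally 0-based
half-open; GFF3 is converted on read/write).  All writers emit plain-text,
diff-able files; round-trips are lossless for in-range values.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .intervals import GeneModel, IntervalSet
from .radial import SurfaceGrid

__all__ = [
    "write_nucleus_table",
    "read_nucleus_table",
    "write_grid",
    "read_grid",
    "write_bed",
    "read_bed",
    "write_gff3",
    "read_gff3",
    "write_json",
    "read_json",
]

_NUCLEUS_REQUIRED = ["cell_id", "x_um", "y_um", "z_um", "layer"]


def write_nucleus_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in _NUCLEUS_REQUIRED if c not in table.columns]
    if missing:
        raise ValidationError(f"nucleus table missing columns {missing}")
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_nucleus_table(path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse nucleus table: {exc}") from exc
    missing = [c for c in _NUCLEUS_REQUIRED if c not in table.columns]
    if missing:
        raise ParseError(f"nucleus table missing columns {missing}")
    channels = [c for c in table.columns if c not in _NUCLEUS_REQUIRED]
    if not channels:
        raise ParseError("nucleus table has no channel columns")
    if table["cell_id"].duplicated().any():
        dup = table.index[table["cell_id"].duplicated()][0]
        raise ParseError("duplicate cell_id", line=int(dup) + 2)
    coords = table[["x_um", "y_um", "z_um"]].to_numpy()
    bad = ~np.all(np.isfinite(coords.astype(float)), axis=1)
    if bad.any():
        raise ParseError("non-finite coordinates", line=int(np.argmax(bad)) + 2)
    for ch in channels:
        vals = table[ch].to_numpy(dtype=float)
        neg = ~(np.isfinite(vals) & (vals >= 0))
        if neg.any():
            raise ParseError(
                f"channel {ch!r} has negative or non-finite intensity",
                line=int(np.argmax(neg)) + 2,
            )
    return table


def write_grid(grid: SurfaceGrid, path) -> None:
    """Surface grid as TSV matrix (``.tsv``) or 32-bit TIFF (``.tif``),
    with pixel size and origin embedded."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(
            path,
            grid.data.astype(np.float32),
            description=json.dumps(
                {"pixel_size_um": grid.pixel_size, "origin_um": list(grid.origin)}
            ),
        )
        return
    with open(path, "w") as fh:
        fh.write(f"# pixel_size_um\t{grid.pixel_size!r}\n")
        fh.write(f"# origin_um\t{grid.origin[0]!r}\t{grid.origin[1]!r}\n")
        np.savetxt(fh, grid.data, delimiter="\t", fmt="%.9g")


def read_grid(path) -> SurfaceGrid:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray()
            try:
                meta = json.loads(page.description)
            except (json.JSONDecodeError, TypeError) as exc:
                raise ParseError(f"TIFF lacks grid metadata: {exc}") from exc
        ps = meta["pixel_size_um"]
        if not np.isscalar(ps):
            raise ParseError("anisotropic pixel size not supported")
        return SurfaceGrid(data=np.asarray(data, float), pixel_size=float(ps),
                           origin=tuple(meta["origin_um"]))
    pixel_size = origin = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "pixel_size_um":
                    pixel_size = float(parts[1])
                elif parts and parts[0] == "origin_um":
                    origin = (float(parts[1]), float(parts[2]))
                continue
            if line.strip():
                try:
                    rows.append([float(v) for v in line.split("\t")])
                except ValueError as exc:
                    raise ParseError(f"bad grid row: {exc}", line=lineno) from exc
    if pixel_size is None or origin is None:
        raise ParseError("grid TSV missing pixel_size_um/origin_um header")
    return SurfaceGrid(data=np.array(rows), pixel_size=pixel_size, origin=origin)


def write_bed(s: IntervalSet, path) -> None:
    """BED6: name column carries the direction/label, score the posterior
    probability ('.' when absent), strand is '.' (interval sets are
    strand-free)."""
    with open(path, "w") as fh:
        for rec in s.df.itertuples(index=False):
            score = "." if (isinstance(rec.score, float) and math.isnan(rec.score)) else repr(
                float(rec.score)
            )
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t{score}\t.\n")


def read_bed(path) -> IntervalSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED line has fewer than 3 columns", line=lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinates: {exc}", line=lineno) from exc
            if not 0 <= start < end:
                raise ParseError(f"need 0 <= start < end, got {start}, {end}", line=lineno)
            name = parts[3] if len(parts) > 3 else "."
            score = np.nan
            if len(parts) > 4 and parts[4] != ".":
                try:
                    score = float(parts[4])
                except ValueError as exc:
                    raise ParseError(f"bad score: {exc}", line=lineno) from exc
            rows.append((parts[0], start, end, name, score))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"]))


def write_gff3(genes: list[GeneModel], path) -> None:
    """Gene models as GFF3 (1-based closed coordinates on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsamquant\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for j, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tsamquant\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{j};Parent={g.gene_id}\n"
                )
            for feat, span in (("five_prime_UTR", g.five_utr), ("three_prime_UTR", g.three_utr)):
                if span is not None:
                    fh.write(
                        f"{g.chrom}\tsamquant\t{feat}\t{span[0] + 1}\t{span[1]}\t.\t{g.strand}\t.\t"
                        f"ID={g.gene_id}.{feat};Parent={g.gene_id}\n"
                    )


def read_gff3(path) -> list[GeneModel]:
    """Read gene models (gene + exon/UTR children) from GFF3, converting
    1-based closed coordinates to 0-based half-open."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
        )
    except Exception as exc:
        raise ParseError(f"cannot parse GFF3: {exc}") from exc
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = tuple(
            (e.start - 1, e.end) for e in db.children(g, featuretype="exon", order_by="start")
        )
        five = three = None
        for u in db.children(g, featuretype="five_prime_UTR"):
            five = (u.start - 1, u.end)
        for u in db.children(g, featuretype="three_prime_UTR"):
            three = (u.start - 1, u.end)
        genes.append(
            GeneModel(
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand,
                gene_id=g.id,
                exons=exons,
                five_utr=five,
                three_utr=three,
            )
        )
    return genes


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
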