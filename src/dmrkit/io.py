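"""Plain-text format surfaces: CpG report TSV, feature BED6, gene table
TSV, expression counts TSV, group map TSV and truth JSON.

Coordinates are 0-based half-open everywhere, matching BED. CpG strand is
collapsed: counts are assumed pre-merged onto the + strand C of each CpG.
Round trips are byte-stable after one write-read-write cycle.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .simulate import (PlantedCliff, PlantedDMR, PlantedSegment, SyntheticTruth)
from .types import (CpGMethylomeMatrix, ExpressionCounts, GeneModel,
                    GenomicFeature, ParseError)

PathLike = Union[str, Path]

CPG_HEADER = ["chrom", "pos0", "strand", "meth_reads", "total_reads"]


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


# ---------------------------------------------------------------------------
# CpG reports


def write_cpg_report(m: CpGMethylomeMatrix, path: PathLike,
                     sample: Optional[str] = None) -> None:
    """Write one sample (narrow dialect) or all samples (wide dialect)."""
    path = Path(path)
    with open(path, "w") as fh:
        if sample is not None:
            si = m.samples.index(sample)
            fh.write("\t".join(CPG_HEADER) + "\n")
            for i in range(m.n_sites):
                fh.write(f"{m.chrom[i]}\t{m.pos[i]}\t+\t"
                         f"{m.meth[i, si]}\t{m.total[i, si]}\n")
        else:
            cols = ["chrom", "pos0", "strand"]
            for s in m.samples:
                cols += [f"{s}.meth", f"{s}.total"]
            fh.write("\t".join(cols) + "\n")
            for i in range(m.n_sites):
                row = [str(m.chrom[i]), str(m.pos[i]), "+"]
                for si in range(len(m.samples)):
                    row += [str(m.meth[i, si]), str(m.total[i, si])]
                fh.write("\t".join(row) + "\n")


def _parse_count(tok: str, path, ln: int, what: str) -> int:
    try:
        v = int(tok)
    except ValueError:
        raise ParseError(f"{path}:{ln}: non-integer {what} {tok!r}") from None
    return v


def read_cpg_report(path: PathLike, groups: Optional[dict] = None,
                    sample: Optional[str] = None,
                    sort: bool = False) -> CpGMethylomeMatrix:
    """Read a wide multi-sample report, or a narrow single-sample report
    when ``sample`` is given. Unsorted input is rejected unless ``sort``."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if sample is not None:
            if header != CPG_HEADER:
                raise ParseError(f"{path}:1: unexpected header for narrow dialect")
            samples = [sample]
            pairs = [(3, 4)]
        else:
            if header[:3] != ["chrom", "pos0", "strand"]:
                raise ParseError(f"{path}:1: unexpected header")
            rest = header[3:]
            if len(rest) % 2 != 0:
                raise ParseError(f"{path}:1: dangling sample column")
            samples = []
            pairs = []
            for i in range(0, len(rest), 2):
                name = rest[i].rsplit(".", 1)[0]
                if not rest[i].endswith(".meth") or not rest[i + 1].endswith(".total"):
                    raise ParseError(f"{path}:1: expected <sample>.meth/<sample>.total pairs")
                samples.append(name)
                pairs.append((3 + i, 4 + i))
        chroms, poss = [], []
        meth_rows, tot_rows = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 + 2 * len(samples):
                raise ParseError(f"{path}:{ln}: truncated line")
            chroms.append(parts[0])
            poss.append(_parse_count(parts[1], path, ln, "position"))
            me_row, to_row = [], []
            for (mi, ti) in pairs:
                me = _parse_count(parts[mi], path, ln, "meth count")
                to = _parse_count(parts[ti], path, ln, "total count")
                if me > to:
                    raise ParseError(
                        f"{path}:{ln}: methylated reads ({me}) exceed total ({to})")
                if me < 0 or to < 0:
                    raise ParseError(f"{path}:{ln}: negative count")
                me_row.append(me)
                to_row.append(to)
            meth_rows.append(me_row)
            tot_rows.append(to_row)
    chrom = np.array(chroms, dtype=object)
    pos = np.array(poss, dtype=np.int64)
    meth = np.array(meth_rows, dtype=np.int64).reshape(len(poss), len(samples))
    total = np.array(tot_rows, dtype=np.int64).reshape(len(poss), len(samples))
    order = np.lexsort((pos, chrom.astype(str)))
    if not np.array_equal(order, np.arange(len(order))):
        if not sort:
            raise ParseError(f"{path}: sites not sorted by (chrom, pos); pass sort=True")
        chrom, pos, meth, total = chrom[order], pos[order], meth[order], total[order]
    if groups is None:
        groups = {s: s.rsplit("_", 1)[0] for s in samples}
    return CpGMethylomeMatrix(chrom, pos, samples, groups, meth, total)


def merge_sample_reports(paths_by_sample: dict[str, PathLike],
                         groups: Optional[dict] = None) -> CpGMethylomeMatrix:
    """Merge narrow per-sample reports on the union of sites (absent sites
    get zero coverage)."""
    singles = {s: read_cpg_report(p, sample=s) for s, p in paths_by_sample.items()}
    keys = sorted({(str(c), int(p)) for m in singles.values()
                   for c, p in zip(m.chrom, m.pos)})
    index = {k: i for i, k in enumerate(keys)}
    samples = list(paths_by_sample)
    meth = np.zeros((len(keys), len(samples)), dtype=np.int64)
    total = np.zeros_like(meth)
    for si, s in enumerate(samples):
        m = singles[s]
        for c, p, me, to in zip(m.chrom, m.pos, m.meth[:, 0], m.total[:, 0]):
            i = index[(str(c), int(p))]
            meth[i, si] = me
            total[i, si] = to
    chrom = np.array([k[0] for k in keys], dtype=object)
    pos = np.array([k[1] for k in keys], dtype=np.int64)
    if groups is None:
        groups = {s: s.rsplit("_", 1)[0] for s in samples}
    return CpGMethylomeMatrix(chrom, pos, samples, groups, meth, total)


# ---------------------------------------------------------------------------
# feature BED6


def _attr_string(f: GenomicFeature) -> str:
    parts = [f.feature_class]
    for k in sorted(f.attributes):
        parts.append(f"{k}={_fmt(f.attributes[k])}")
    return ";".join(parts)


def write_feature_bed(features: Sequence[GenomicFeature], path: PathLike) -> None:
    with open(path, "w") as fh:
        for f in features:
            if f.feature_class == "DMR":
                score = int(round(1000 * abs(float(f.attributes.get("delta_me", 0)))))
            else:
                score = 0
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{_attr_string(f)}\t{score}\t.\n")


def _parse_attr_value(v: str):
    try:
        return int(v)
    except ValueError:
        pass
    try:
        f = float(v)
        return f
    except ValueError:
        return v


def read_feature_bed(path: PathLike) -> list[GenomicFeature]:
    path = Path(path)
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: expected >= 4 BED columns")
            chrom = parts[0]
            start = _parse_count(parts[1], path, ln, "start")
            end = _parse_count(parts[2], path, ln, "end")
            if start >= end:
                raise ParseError(f"{path}:{ln}: start >= end")
            tokens = parts[3].split(";")
            fclass = tokens[0]
            attrs = {}
            for tok in tokens[1:]:
                if not tok:
                    continue
                if "=" not in tok:
                    raise ParseError(f"{path}:{ln}: malformed attribute {tok!r}")
                k, v = tok.split("=", 1)
                attrs[k] = _parse_attr_value(v)
            try:
                out.append(GenomicFeature(chrom, start, end, fclass, attrs))
            except ParseError as e:
                raise ParseError(f"{path}:{ln}: {e}") from None
    return out


# ---------------------------------------------------------------------------
# gene table


GENE_HEADER = ["gene_id", "chrom", "start", "end", "strand", "biotype", "is_tf"]


def write_gene_table(genes: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_HEADER) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t"
                     f"{g.biotype}\t{1 if g.is_tf else 0}\n")


def read_gene_table(path: PathLike) -> list[GeneModel]:
    path = Path(path)
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GENE_HEADER:
            raise ParseError(f"{path}:1: unexpected gene table header")
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ParseError(f"{path}:{ln}: expected 7 columns")
            try:
                out.append(GeneModel(parts[0], parts[1],
                                     _parse_count(parts[2], path, ln, "start"),
                                     _parse_count(parts[3], path, ln, "end"),
                                     parts[4], parts[5], parts[6] == "1"))
            except ParseError as e:
                raise ParseError(f"{path}:{ln}: {e}") from None
    return out


# ---------------------------------------------------------------------------
# expression counts and groups


def write_counts(counts: ExpressionCounts, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(counts.samples) + "\n")
        for i, g in enumerate(counts.gene_ids):
            fh.write(g + "\t" + "\t".join(str(c) for c in counts.counts[i]) + "\n")


def read_counts(path: PathLike, groups: Optional[dict] = None) -> ExpressionCounts:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["gene_id"]:
            raise ParseError(f"{path}:1: first column must be gene_id")
        samples = header[1:]
        gene_ids, rows = [], []
        seen = set()
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(samples) + 1:
                raise ParseError(f"{path}:{ln}: wrong column count")
            if parts[0] in seen:
                raise ParseError(f"{path}:{ln}: duplicated gene id {parts[0]!r}")
            seen.add(parts[0])
            gene_ids.append(parts[0])
            row = [_parse_count(t, path, ln, "count") for t in parts[1:]]
            if any(c < 0 for c in row):
                raise ParseError(f"{path}:{ln}: negative count")
            rows.append(row)
    counts = (np.array(rows, dtype=np.int64) if rows
              else np.zeros((0, len(samples)), dtype=np.int64))
    if groups is None:
        groups = {s: s.rsplit("_", 1)[0] for s in samples}
    return ExpressionCounts(gene_ids, samples, counts, groups)


def write_groups(groups: dict[str, str], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s in groups:
            fh.write(f"{s}\t{groups[s]}\n")


def read_groups(path: PathLike) -> dict[str, str]:
    path = Path(path)
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample", "group"]:
            raise ParseError(f"{path}:1: unexpected group map header")
        for line in fh:
            s, g = line.rstrip("\n").split("\t")
            out[s] = g
    return out


# ---------------------------------------------------------------------------
# truth JSON


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_truth(truth: SyntheticTruth, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1, default=_json_default)


def read_truth(path: PathLike) -> SyntheticTruth:
    with open(path) as fh:
        raw = json.load(fh)
    truth = SyntheticTruth()
    truth.planted_dmrs = [PlantedDMR(**d) for d in raw["planted_dmrs"]]
    for key, cls in (("planted_umrs", PlantedSegment),
                     ("planted_lmrs", PlantedSegment),
                     ("planted_dmvs", PlantedSegment)):
        setattr(truth, key, {g: [cls(**s) for s in segs]
                             for g, segs in raw[key].items()})
    truth.planted_cliffs = [PlantedCliff(**c) for c in raw["planted_cliffs"]]
    truth.de_genes = raw["de_genes"]
    truth.dedm_links = {g: tuple(v) for g, v in raw["dedm_links"].items()}
    truth.peak_truth = {t: [tuple(iv) for iv in ivs]
                        for t, ivs in raw["peak_truth"].items()}
    return truth
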