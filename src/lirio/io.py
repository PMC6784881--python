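"""Text-format I/O: orthogroup tables, clade maps, anchors, BED, VCF.

Conventions:
  * orthogroup TSV — one row per orthogroup,
    ``OG_id<TAB>species:gene1,gene2;species2:gene3`` (OrthoFinder-like);
  * clade map — 2-column TSV ``species<TAB>clade``;
  * anchors — TSV ``gene_a<TAB>chrom_a<TAB>index_a<TAB>gene_b<TAB>chrom_b<TAB>index_b``;
  * gene positions — BED (chrom, start, end, gene, score, strand; 0-based
    half-open, converted to ordinal ranks by start) or a 4-column rank TSV;
  * SNP matrices — minimal VCF (CHROM, POS, REF, ALT, GT) read through
    cyvcf2, or a plain TSV matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .conflict import GeneTopologyResult, Orthogroup, SupportCounts
from .popgen import SNPMatrix
from .synteny import AnchorPair, Genome, SyntenyBlock

__all__ = ["read_orthogroups", "write_orthogroups", "read_clade_map",
           "write_clade_map", "read_anchors", "write_anchors",
           "read_genome_bed", "read_genome_ranks", "write_genome_ranks",
           "read_vcf", "write_vcf", "write_snp_tsv", "read_snp_tsv",
           "write_gene_results", "write_support_summary", "write_blocks",
           "write_depths", "read_group_file"]


# -- orthogroups -------------------------------------------------------

def write_orthogroups(orthogroups: list[Orthogroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        for og in orthogroups:
            cell = ";".join(f"{sp}:{','.join(genes)}"
                            for sp, genes in sorted(og.genes.items()) if genes)
            fh.write(f"{og.id}\t{cell}\n")


def read_orthogroups(path: str | Path) -> list[Orthogroup]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            og_id, cell = line.split("\t", 1)
            genes: dict[str, list[str]] = {}
            for part in cell.split(";"):
                if not part:
                    continue
                sp, gl = part.split(":", 1)
                genes[sp] = [g for g in gl.split(",") if g]
            out.append(Orthogroup(og_id, genes))
    return out


# -- clade map / group file -------------------------------------------

def read_clade_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["species", "clade"],
                     comment="#", dtype=str)
    return dict(zip(df["species"], df["clade"]))


def write_clade_map(clade_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(clade_map.items())).to_csv(
        path, sep="\t", header=False, index=False)


read_group_file = read_clade_map  # sample -> population group, same format


# -- anchors and genomes ----------------------------------------------

def write_anchors(anchors: list[AnchorPair], genome_a: Genome, genome_b: Genome,
                  path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in anchors:
            la, lb = genome_a.loci[p.gene_a], genome_b.loci[p.gene_b]
            fh.write(f"{la.gene}\t{la.chrom}\t{la.index}\t"
                     f"{lb.gene}\t{lb.chrom}\t{lb.index}\n")


def read_anchors(path: str | Path) -> list[AnchorPair]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_a", "chrom_a", "index_a",
                            "gene_b", "chrom_b", "index_b"], dtype=str)
    return [AnchorPair(a, b) for a, b in zip(df["gene_a"], df["gene_b"])]


def read_genome_bed(path: str | Path) -> Genome:
    """BED (0-based half-open) to ordinal gene ranks ordered by start."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "gene"])
    chroms: dict[str, list[str]] = {}
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        chroms[str(chrom)] = [str(g) for g in sub["gene"]]
    return Genome(chroms)


def write_genome_ranks(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, genes in genome.chromosomes.items():
            for i, g in enumerate(genes):
                fh.write(f"{g}\t{chrom}\t{i}\t+\n")


def read_genome_ranks(path: str | Path) -> Genome:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene", "chrom", "index", "strand"], dtype=str)
    df["index"] = df["index"].astype(int)
    chroms: dict[str, list[str]] = {}
    for chrom, sub in df.sort_values(["chrom", "index"]).groupby("chrom", sort=True):
        chroms[str(chrom)] = list(sub["gene"])
    return Genome(chroms)


# -- SNP matrices ------------------------------------------------------

def write_vcf(m: SNPMatrix, path: str | Path, chrom: str = "1") -> None:
    """Minimal VCF: CHROM, POS, REF, ALT and GT fields only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom},length={m.L}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.samples) + "\n")
        for j, pos in enumerate(m.positions):
            gts = []
            for i in range(m.n_samples):
                v = int(m.matrix[i, j])
                if m.ploidy == 1:
                    gts.append("." if v < 0 else str(v))
                else:
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}.get(v, "./."))
            fh.write(f"{chrom}\t{int(pos) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def read_vcf(path: str | Path, L: int, ploidy: int = 1) -> SNPMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions, rows = [], []
    for rec in vcf:
        positions.append(rec.POS - 1)
        col = []
        for g in rec.genotypes:
            alleles = [a for a in g[:-1] if a is not None]
            if not alleles or any(a < 0 for a in alleles):
                col.append(-1)
            else:
                col.append(sum(alleles))
        rows.append(col)
    matrix = (np.array(rows, dtype=np.int8).T if rows
              else np.zeros((len(samples), 0), dtype=np.int8))
    return SNPMatrix(samples, np.array(positions, dtype=np.int64), matrix,
                     ploidy=ploidy, L=L)


def write_snp_tsv(m: SNPMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.matrix, index=m.samples,
                      columns=[str(p) for p in m.positions])
    df.to_csv(path, sep="\t", index_label="sample")


def read_snp_tsv(path: str | Path, L: int, ploidy: int = 1) -> SNPMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return SNPMatrix(list(df.index.astype(str)),
                     np.array([int(c) for c in df.columns]),
                     df.to_numpy(dtype=np.int8), ploidy=ploidy, L=L)


# -- result tables -----------------------------------------------------

def write_gene_results(results: list[GeneTopologyResult], path: str | Path) -> None:
    rows = [{
        "orthogroup": r.orthogroup_id,
        "lnL1": r.lnl[0], "lnL2": r.lnl[1], "lnL3": r.lnl[2],
        "d12": r.d12, "d13": r.d13, "d23": r.d23,
        "supported": r.supported, "outlier": r.outlier,
    } for r in results]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_support_summary(sc: SupportCounts, path: str | Path) -> None:
    payload = {
        "counts": list(sc.counts), "total": sc.total,
        "percentages": list(sc.percentages),
        "chi2": sc.chi2, "df": sc.df, "p": sc.p,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_blocks(blocks: list[SyntenyBlock], path: str | Path) -> None:
    rows = []
    for i, b in enumerate(blocks):
        rows.append({
            "block": f"b{i:04d}", "chrom_a": b.chrom_a, "chrom_b": b.chrom_b,
            "orientation": b.orientation, "size": b.size,
            "start_a": b.span_a[0], "end_a": b.span_a[1],
            "start_b": b.span_b[0], "end_b": b.span_b[1],
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_depths(depths: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(sorted(depths.items()), columns=["gene", "depth"]).to_csv(
        path, sep="\t", index=False)
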