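"""Deterministic synthetic annotation fixtures.

Generates a small random genome with non-overlapping multi-exon gene
models, plus the auxiliary tables (paralogs, similarity regions,
red-herring annotations), all loadable by :func:`annotation.load_annotation`.
When ``plant_splice_consensus`` is set, every intron carries canonical
GT..AG dinucleotides in transcription sense so the fusion simulator always
finds admissible breakpoints.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype="S1")


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (80, 300)
    intergenic_gap: tuple[int, int] = (300, 1200)
    plant_splice_consensus: bool = True
    n_noncoding: int = 0
    n_paralog_pairs: int = 0
    n_similar_pairs: int = 0
    n_overlap_pairs: int = 0
    normal_pairs: tuple[tuple[str, str], ...] = ()
    gene_label_rows: tuple[tuple[str, str], ...] = ()  # (symbol, label)
    seed: int = 0
    extra_paralog_rows: tuple[tuple[str, str], ...] = field(default=())


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _plant(seq: np.ndarray, pos: int, dinuc: str) -> None:
    seq[pos : pos + 2] = np.frombuffer(dinuc.encode(), dtype="S1")


def generate_fixture(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Write FASTA, GTF, paralog/similarity/annotation TSVs to ``out_dir``.

    Returns a dict of the written paths keyed by
    ``fasta``/``gtf``/``paralogs``/``similarity``/``annots``.
    Deterministic in ``spec.seed``: identical specs produce byte-identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    chrom_seqs = {c: _random_dna(rng, spec.chrom_length) for c in chrom_names}

    # round-robin genes across chromosomes
    genes = []  # dicts: gene_id symbol chrom strand biotype exons
    cursors = {c: 0 for c in chrom_names}
    n_total = spec.n_genes
    for i in range(n_total):
        chrom = chrom_names[i % spec.n_chroms]
        seq = chrom_seqs[chrom]
        gap = int(rng.integers(*spec.intergenic_gap))
        n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exon_lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1, size=n_exons)
        intron_lens = rng.integers(
            spec.intron_length[0], spec.intron_length[1] + 1, size=max(n_exons - 1, 0)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom] + gap
        end = start + int(exon_lens.sum() + intron_lens.sum())
        if end + 2 > len(seq):
            raise FixtureError(
                f"gene {i} does not fit on {chrom}: need {end + 2} bases, "
                f"have {len(seq)}; increase chrom_length or reduce n_genes"
            )
        exons = []
        pos = start
        for j, elen in enumerate(exon_lens):
            exons.append((pos, pos + int(elen)))
            pos += int(elen)
            if j < n_exons - 1:
                ilen = int(intron_lens[j])
                if spec.plant_splice_consensus:
                    if strand == "+":
                        _plant(seq, pos, "GT")  # donor side of the intron
                        _plant(seq, pos + ilen - 2, "AG")  # acceptor side
                    else:
                        # transcription runs right-to-left: GT..AG in
                        # transcription sense is CT..AC in genome sense
                        _plant(seq, pos, "CT")
                        _plant(seq, pos + ilen - 2, "AC")
                pos += ilen
        cursors[chrom] = end
        biotype = "lincRNA" if i >= n_total - spec.n_noncoding else "protein_coding"
        genes.append(
            {
                "gene_id": f"G{i:03d}",
                "symbol": f"SYM{i:03d}",
                "chrom": chrom,
                "strand": strand,
                "biotype": biotype,
                "exons": exons,
            }
        )

    # optional genes overlapping earlier genes (for lenient-scoring proxies)
    for k in range(spec.n_overlap_pairs):
        host = genes[k % len(genes)]
        hstart = host["exons"][0][0]
        gid = len(genes)
        exons = [(hstart + 10, hstart + 10 + 200)]
        genes.append(
            {
                "gene_id": f"G{gid:03d}",
                "symbol": f"OVL{k:03d}",
                "chrom": host["chrom"],
                "strand": host["strand"],
                "biotype": "protein_coding",
                "exons": exons,
            }
        )

    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom in chrom_names:
            fh.write(f">{chrom}\n")
            fh.write(textwrap.fill(chrom_seqs[chrom].tobytes().decode(), 60))
            fh.write("\n")

    gtf_path = out_dir / "genes.gtf"
    with open(gtf_path, "w") as fh:
        for g in genes:
            span = (g["exons"][0][0], g["exons"][-1][1])
            base_attr = (
                f'gene_id "{g["gene_id"]}"; gene_name "{g["symbol"]}"; '
                f'gene_biotype "{g["biotype"]}";'
            )
            fh.write(
                "\t".join(
                    [
                        g["chrom"],
                        "fixture",
                        "gene",
                        str(span[0] + 1),
                        str(span[1]),
                        ".",
                        g["strand"],
                        ".",
                        base_attr,
                    ]
                )
                + "\n"
            )
            tx_id = g["gene_id"] + ".t1"
            tx_attr = base_attr + f' transcript_id "{tx_id}";'
            fh.write(
                "\t".join(
                    [
                        g["chrom"],
                        "fixture",
                        "transcript",
                        str(span[0] + 1),
                        str(span[1]),
                        ".",
                        g["strand"],
                        ".",
                        tx_attr,
                    ]
                )
                + "\n"
            )
            for s, e in g["exons"]:
                fh.write(
                    "\t".join(
                        [
                            g["chrom"],
                            "fixture",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            g["strand"],
                            ".",
                            tx_attr,
                        ]
                    )
                    + "\n"
                )

    coding = [g for g in genes if g["biotype"] == "protein_coding"]
    paralog_path = out_dir / "paralogs.tsv"
    with open(paralog_path, "w") as fh:
        chosen = rng.permutation(len(coding))
        for k in range(spec.n_paralog_pairs):
            a, b = coding[chosen[2 * k]], coding[chosen[2 * k + 1]]
            fh.write(f"{a['symbol']}\t{b['symbol']}\n")
        for a, b in spec.extra_paralog_rows:
            fh.write(f"{a}\t{b}\n")

    similarity_path = out_dir / "similarity.tsv"
    with open(similarity_path, "w") as fh:
        chosen = rng.permutation(len(genes))
        for k in range(spec.n_similar_pairs):
            a, b = genes[chosen[2 * k]], genes[chosen[2 * k + 1]]
            sa, ea = a["exons"][0]
            sb, eb = b["exons"][0]
            fh.write(
                f"{a['gene_id']}\t{b['gene_id']}\t"
                f"{a['chrom']}:{sa}-{ea}\t{b['chrom']}:{sb}-{eb}\n"
            )

    annot_path = out_dir / "fusion_annots.tsv"
    with open(annot_path, "w") as fh:
        for a, b in spec.normal_pairs:
            fh.write(f"{a}--{b}\tNORMAL\n")
        for sym, label in spec.gene_label_rows:
            fh.write(f"{sym}\t{label}\n")

    return {
        "fasta": fasta_path,
        "gtf": gtf_path,
        "paralogs": paralog_path,
        "similarity": similarity_path,
        "annots": annot_path,
    }
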