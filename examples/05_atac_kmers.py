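"""Chromatin-accessibility features: k-mer deviation z-scores.

Builds a toy peak x cell count matrix with one 7-mer enriched in half
the cells, scores every peak for canonical 7-mers, computes
background-standardized accessibility deviations, and shows that the
planted 7-mer separates the two cell groups. Also exports the top k-mers
in MEME format for external motif annotation.
"""

import numpy as np

import elastree as et
from elastree.atac import (PeakKmerMatrix, atac_feature_prep,
                           canonical_kmer, export_kmers_meme,
                           kmer_deviations, match_kmers)

counts, seqs, peak_ids, truth = et.make_toy_atac(
    n_peaks=200, n_cells=200, enrichment=2.0, seed=1)
pk = match_kmers(seqs, k=7, peak_ids=peak_ids)
print(f"{len(seqs)} peaks scored for {len(pk.kmers)} canonical 7-mers")

planted = canonical_kmer(truth["planted_kmer"])
j = pk.kmers.index(planted)
cols = [j] + [c for c in range(len(pk.kmers)) if c != j][:50]
sub = PeakKmerMatrix(matrix=pk.matrix[:, cols], peak_ids=pk.peak_ids,
                     kmers=[pk.kmers[c] for c in cols], k=7,
                     gc_content=pk.gc_content)
dev = kmer_deviations(counts, sub, n_background=50, seed=2)

gaps = np.abs(dev.zscores[truth["group"]].mean(axis=0)
              - dev.zscores[~truth["group"]].mean(axis=0))
ranked = np.argsort(-gaps)
print("7-mers ranked by group z-score separation:")
for r in ranked[:3]:
    mark = "  <- planted" if sub.kmers[r] == planted else ""
    print(f"  {sub.kmers[r]}  gap={gaps[r]:.2f}{mark}")

feats = atac_feature_prep(dev, n_pcs=10, exclude_first=True)
print(f"feature matrix for the trajectory pipeline: {feats.shape} "
      "(standardized z-scores, PCs 2-11)")

export_kmers_meme([sub.kmers[r] for r in ranked[:3]], "top_kmers.meme")
print("top_kmers.meme: top k-mers for external motif annotation")
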