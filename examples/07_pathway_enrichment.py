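"""Hypergeometric over-representation of a metabolite hit list.

The bundled library holds five pathways (sphingolipid, taurine/hypotaurine,
nitrogen, cysteine/methionine, glycerophospholipid metabolism) inside a
100-metabolite universe; the hit list is the bundled annotation table's
HMDB ids.  p-values are exact hypergeometric upper tails.
"""

import chemometab as cm
from chemometab.pathways import results_frame

library = cm.bundled_library()
hits = cm.bundled_annotations()["hmdb_id"].tolist()
print(f"universe: {len(library.universe)} metabolites, hit list: {len(hits)}")

results = cm.enrich(hits, library, alpha=0.05)
frame = results_frame(results)
print(frame[["pathway_id", "name", "k", "K", "p_value", "significant"]]
      .round({"p_value": 5}).to_string(index=False))
# k of K members hit; 'significant' compares the raw p-value with alpha=0.05
print(f"hand check: p(k=3 of K=5, n=4, N=20) = {cm.ora_pvalue(3, 5, 4, 20):.5f} (= 155/4845)")
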