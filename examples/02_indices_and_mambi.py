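"""Biodiversity descriptors and ecological quality under a library gap.

Runs the full pipeline on a synthetic two-season survey: richness S, Shannon
H and AMBI per sample under the complete (morphological) and the
barcode-reduced database, M-AMBI scores against shared reference conditions
and the resulting WFD quality classes.
"""

from barcodegap import apulia_like_config, simulate_catalog, simulate_communities
from barcodegap.comparison import PipelineConfig, run_pipeline

cfg = apulia_like_config(seed=1)
catalog = simulate_catalog(cfg)
community = simulate_communities(cfg, catalog)
result = run_pipeline(catalog, community, PipelineConfig(seed=1))

cols = ["site_id", "season", "database", "s", "h", "ambi", "score",
        "eqs_class"]
fall = result.metrics[result.metrics.season == "fall"]
print(fall[cols].to_string(index=False,
                           float_format=lambda v: f"{v:.3f}"))
print("\nEach row is one sample under one database: S counts species, H is"
      "\nShannon diversity (log base 2), AMBI rises from 0 (all sensitive"
      "\nspecies) to 6 (all first-order opportunists), and the M-AMBI score"
      "\nin [0, 1] maps to the five WFD classes. Reduced rows lose the"
      "\nnon-barcoded species, so S and H drop and classes can slip.")
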