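"""Generate the synthetic study that all downstream analyses consume.

The layout mirrors a two-sample MR mediation study of a binary oral-disease
exposure on a binary cardiac outcome: one exposure GWAS (prevalence 0.25,
log-odds effects), one outcome GWAS (prevalence 0.10) with its own risk loci
(so the reverse direction has instruments), a covariate comorbidity that
shares liability with the exposure but does not affect the outcome, and a
panel of eight candidate mediators — five on a real causal path with
distinct mediated proportions (two of them binary), three null in different
ways.  Every GWAS uses its own non-overlapping cohort of n = 20,000.

Writes summary-statistics TSVs, the LD matrix, and the generating truth to
results/synthetic_study/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mrmediate import MediatorSpec, SimConfig, simulate_chain, write_sumstats
from mrmediate.pipeline import _jsonify

OUT = ROOT / "results" / "synthetic_study"

MEDIATORS = (
    MediatorSpec("weight_like", 0.30, 0.45, n_snps=20),
    MediatorSpec("il17_like", 0.25, 0.30, n_snps=20),
    MediatorSpec("tnf_like", 0.22, 0.25, n_snps=20),
    MediatorSpec("corath_like", 0.20, 0.25, n_snps=20,
                 trait_type="binary", prevalence=0.10),
    MediatorSpec("hypertension_like", 0.18, 0.22, n_snps=20,
                 trait_type="binary", prevalence=0.25),
    MediatorSpec("null_uncaused", 0.00, 0.30, n_snps=20),
    MediatorSpec("null_no_effect", 0.30, 0.00, n_snps=20),
    MediatorSpec("null_inert", 0.00, 0.00, n_snps=20),
    MediatorSpec("comorbidity", 0.30, 0.00, n_snps=20),  # MVMR covariate
)

CONFIG = SimConfig(
    seed=2024,
    n_exposure_snps=30, h2_exposure=0.10,
    n_outcome_snps=20, h2_outcome=0.08,
    theta_xy_direct=0.10,
    mediators=MEDIATORS,
    exposure_trait_type="binary", exposure_prevalence=0.25,
    outcome_trait_type="binary", outcome_prevalence=0.10,
)


def main() -> None:
    sim = simulate_chain(CONFIG)
    OUT.mkdir(parents=True, exist_ok=True)
    for name, ss in sim.sumstats.items():
        write_sumstats(ss, OUT / f"{name}.tsv")
    sim.ld.to_tsv(OUT / "ld.tsv")
    with open(OUT / "truth.json", "w") as fh:
        json.dump(_jsonify(sim.truth), fh, indent=2)

    t = sim.truth
    print(f"wrote {len(sim.sumstats)} summary tables to {OUT}")
    print(f"true total effect (liability scale): {t['theta_total']:.4f}")
    print("true mediated proportions:")
    for name, p in sorted(t["proportion"].items(), key=lambda kv: -kv[1]):
        print(f"  {name:20s} {100 * p:5.1f}%")


if __name__ == "__main__":
    main()
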