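#!/usr/bin/env python
"""Parameter-recovery benchmarks of the screening and network stages.

Screening: sensitivity and empirical FDR over the planted gene (log2FC 2)
and metabolite (1.5 pooled-SD shift) features at n = 6 + 6, 20 seeds.

Networks: adjusted Rand index between the integrated Girvan-Newman
partition and the three planted cross-omic blocks (loading 0.95, 12
matched subjects), and the rate at which planted hub features reach the
top MCC decile, 25 seeds.
"""

from pathlib import Path

from ammonet.benchmarks import network_recovery, screening_recovery

SEED = 42
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    screen = screening_recovery(n_seeds=20, base_seed=SEED)
    screen.per_seed.to_csv(RESULTS / "recovery_screening.tsv", sep="\t",
                           index=False, float_format="%.4f")
    print(f"screening over 20 seeds: mean sensitivity "
          f"{screen.mean_sensitivity:.3f}, mean empirical FDR "
          f"{screen.mean_fdr:.3f} (genes+metabolites pooled)")
    print("  genes at log2FC 2 separate almost every time; the exact-test "
          "p floor (2/924) under BH over 515 metabolites caps metabolite "
          "recall near zero at a 1.5 SD shift, which drags the pooled "
          "sensitivity below the gene-only level")

    net = network_recovery(n_seeds=25, base_seed=SEED)
    net.per_seed.to_csv(RESULTS / "recovery_network.tsv", sep="\t",
                        index=False, float_format="%.4f")
    print(f"network recovery over 25 seeds: mean ARI {net.mean_ari:.3f}, "
          f"ARI>=0.8 in {net.ari_pass_rate:.0%} of seeds")
    print(f"  hubs in the top MCC decile: {net.hub_fraction_mean:.0%} of "
          f"hub observations (all-three-hubs event: {net.hub_pass_rate:.0%} "
          "of seeds; the factorial MCC scale concentrates the global top "
          "decile inside whichever block lost fewest edges that draw)")


if __name__ == "__main__":
    main()
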