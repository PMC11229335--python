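"""Classify red/white assay colonies and compare two strains.

Simulates six replicates of sectored colonies for a wild-type-like
strain (crossover probability 0.504) and a mutant-like strain (0.61),
classifies every colony from its color and antibiotic-marker phenotype
alone, and prints per-strain crossover percentages (mean +/- SD across
replicates) with a Welch t-test on the difference.
"""

from curtainkit import compare_strains, simulate_colony_assay, tally_outcomes

def run_strain(co_prob, strain, seed):
    probs = {
        ("CO", "sectored"): co_prob,
        ("NCO", "sectored"): (1 - co_prob) * 0.85,
        ("BIR", "sectored"): (1 - co_prob) * 0.1,
        ("chromosome_loss", "sectored"): (1 - co_prob) * 0.05,
    }
    records = simulate_colony_assay(probs, n_colonies=400, n_replicates=6,
                                    seed=seed, strain=strain)
    return tally_outcomes(records, population="sectored")

wt = run_strain(0.504, "WT", seed=1)
mutant = run_strain(0.61, "mutant", seed=2)

for name, tally in (("WT", wt), ("mutant", mutant)):
    print(f"{name:7s}: CO {100 * tally.mean['CO']:.1f} +/- "
          f"{100 * tally.sd['CO']:.1f} %  "
          f"(NCO {100 * tally.mean['NCO']:.1f} %, BIR {100 * tally.mean['BIR']:.1f} %)")

res = compare_strains(wt, mutant, category="CO")
print(f"Welch t-test on CO fractions: t = {res.statistic:.2f}, "
      f"p = {res.pvalue:.2e}")
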