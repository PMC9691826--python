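"""Posterior carrier probabilities from family history, tumour pathology and
genetic tests.

Builds a three-person pedigree in which the proband's mother had a
triple-negative breast tumour at 45 and tested negative for BRCA1, then peels
the pedigree likelihood to get the proband's per-gene carrier posteriors.
A TN tumour shifts weight towards the ER-negative-predominant genes (BRCA1,
BARD1, RAD51C, RAD51D) relative to their population priors, while the
negative BRCA1 test pushes BRCA1 back down.
"""

import pedrisk as pk

model = pk.RiskModel.default("bc")

pedigree = pk.Pedigree([
    pk.Individual(id="father", sex="M", birth_year=1955, censor_age=65),
    pk.Individual(id="mother", sex="F", birth_year=1958, censor_age=62,
                  diagnoses={"bc": 45}, pathology="tn",
                  tests={"BRCA1": "neg"}),
    pk.Individual(id="proband", sex="F", birth_year=1985, censor_age=35,
                  father="father", mother="mother", target=True),
])

posterior = pk.carrier_probabilities(pedigree, model)
prior = model.major_prior()

print(f"{'gene':<10}{'prior':>12}{'posterior':>12}{'ratio':>8}")
for i, gene in enumerate(["none", *model.gene_names]):
    print(f"{gene:<10}{prior[i]:>12.5f}{posterior[gene]:>12.5f}"
          f"{posterior[gene] / prior[i]:>8.2f}")

print("\nRatios > 1 mean the family's history raised that gene's carrier "
      "probability; the mother's TN tumour favours the ER-negative genes.")
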