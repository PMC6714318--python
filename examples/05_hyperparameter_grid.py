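"""Grid-searching the three pipeline hyperparameters.

Sweeps the negation switch kappa, the similarity threshold gamma and the
extractor threshold theta over a synthetic corpus and reports the best
cell. Raising theta demands agreement from more extractors (fewer false
positives, more false negatives); raising gamma makes merging stricter.
"""

from clinex import (
    SimulationSpec,
    detect_negation_spans,
    encode_term,
    flag_negated,
    generate_world,
    grid_tune,
    load_negation_lexicon,
    uniform_omega,
)

spec = SimulationSpec(seed=3, n_docs=30)
lexicon, docs, gold, outputs = generate_world(spec)
neg = load_negation_lexicon()
per_doc = {
    doc.doc_id: {
        ex: [encode_term(t, lexicon)
             for t in flag_negated(outputs[ex][doc.doc_id],
                                   detect_negation_spans(doc.text, neg), doc.text)]
        for ex in outputs
    }
    for doc in docs
}

grid = grid_tune(
    per_doc, gold, uniform_omega(sorted(outputs)),
    kappas=(False, True), gammas=(0.1, 0.5), thetas=(0.2, 0.35, 0.7),
)

print("kappa  gamma  theta  precision  recall  F1")
for row in grid.to_rows():
    print(
        f"{str(row['kappa']):5}  {row['gamma']:.2f}   {row['theta']:.2f}   "
        f"{row['precision']:.3f}      {row['recall']:.3f}   {row['f1']:.3f}"
    )

(cell, metrics) = grid.best
print(
    f"\nbest cell: kappa={cell[0]}, gamma={cell[1]}, theta={cell[2]} "
    f"with F1 = {metrics.f1:.3f}"
)
# ties are broken toward the smaller theta, then smaller gamma, then
# kappa=False.
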