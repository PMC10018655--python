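"""Simulate a paired observer study and run the VGC analysis.

Generates ratings for 25 cases x 5 readers x 10 questions under a latent
quality shift of 0.8 favouring the test condition, then prints per-question
AUC_VGC with fixed-reader and random-reader bootstrap confidence intervals
and the answer-proportion table for the three-step questions.
"""

from ctiq import (LatentRatingModel, bootstrap_vgc, default_rating_design,
                  generate_ratings, proportion_table, true_auc)


def main():
    design = default_rating_design(conditions=("asirv", "dlir"))
    model = LatentRatingModel(delta=0.8)
    ratings = generate_ratings(design, model, seed=42)
    print(f"{len(ratings.data)} ratings; latent ground-truth AUC "
          f"(no case/reader effects) = {true_auc(model):.3f}\n")

    print("question  scale  mode           AUC    95% CI          significant")
    for q in design.questions:
        for mode in ("fixed_reader", "random_reader"):
            r = bootstrap_vgc(ratings, q.id, mode=mode, n_boot=2000, seed=7)
            print(f"{q.id:>8}  {q.scale_size}      {mode:<13} "
                  f"{r.auc:.3f}  [{r.ci_low:.3f}, {r.ci_high:.3f}]  "
                  f"{'yes' if r.significant else 'no'}")

    props = proportion_table(ratings, [q.id for q in design.questions
                                       if q.scale_size == 3])
    print("\nAnswer proportions (three-step questions; 1 = unacceptable,"
          " 3 = fully acceptable):")
    print(props.round(3).to_string())
    print("\nAUC > 0.5 with a CI excluding 0.5 marks questions where the test"
          "\ncondition is rated significantly higher; random-reader intervals"
          "\nare wider because they also resample the reader panel.")


if __name__ == "__main__":
    main()
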