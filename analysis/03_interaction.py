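#!/usr/bin/env python
"""Fit the unadjusted PRS x METs interaction logit on the counts-expanded
cohort and report the coefficients and the Wald test for the interaction."""

from pathlib import Path

from gdrisk.pipeline import interaction_from_counts

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    fit = interaction_from_counts()
    OUT.mkdir(exist_ok=True)
    fit.to_json(OUT / "interaction.json")
    print("unadjusted interaction logit on the counts-expanded cohort "
          f"(n = {fit.n}):")
    print(f"  a (intercept)      = {fit.a:+.3f}")
    print(f"  d (high PRS)       = {fit.d:+.3f}")
    print(f"  e (low METs)       = {fit.e:+.3f}")
    print(f"  f (interaction)    = {fit.f:+.3f}  (SE {fit.se_f:.3f}, "
          f"Wald p = {fit.p_f:.3f})")
    print("\nthe positive f indicates the joint high-PRS / low-activity "
          "excess risk exceeds the product of the marginal effects "
          "(non-additive on the log-odds scale).")


if __name__ == "__main__":
    main()
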