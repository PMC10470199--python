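"""Why PREs cluster: the anchored-loop model in one page.

Two loop anchors on a line draw Gaussian loop lengths; flanking "non-sticky"
(unmethylated) chromatin restricts an anchor to half-Gaussian loops toward
the methylated side.  The mean absolute anchor distance shrinks as anchors
become more inward-restricted -- PREs near the edges of a methylated domain
end up closest.
"""

from polyfold import loopmodel as lm

NAMES = {
    1: "both anchors free        ",
    2: "left anchor inward-only  ",
    3: "both anchors inward-only ",
}

print("configuration                mean |l1 - l2|   closed form")
for which in (1, 2, 3):
    spec = lm.standard_configuration(which, sigma_l=0.3, n_draws=10_000, seed=29)
    mean, se = lm.mean_anchor_distance(spec, with_error=True)
    print(f"{which}: {NAMES[which]}  {mean:.3f} +/- {se:.3f}    "
          f"{lm.closed_form_mean(spec):.3f}")
print("\nAnchors sit 2 line-units apart; restricting loop directions pulls "
      "their expected distance below 2 (printed reference: 2.00, 1.76, 1.52).")
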