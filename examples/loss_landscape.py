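"""Evaluate the threshold-aware losses on a (y, y-hat) grid.

loss_bn penalizes only predictions on the wrong side of the acceptance
threshold t; loss_ft is an absolute-error term active only for truly
failed segmentations (y < t); the combined loss mixes both with MSE.
"""
from glottisqc import LossParams, combined_loss, loss_bn, loss_ft

t = 0.6
cases = [(0.7, 0.8), (0.7, 0.5), (0.3, 0.9), (0.5, 0.4), (0.2, 0.8)]
print(f"t = {t};  (y-hat, y) -> loss_bn, loss_ft, combined(l0=0.5, l1=0.5)")
for yh, y in cases:
    c = combined_loss([yh], [y], LossParams(0.5, 0.5, t))
    print(f"  ({yh:.1f}, {y:.1f}) -> {loss_bn([yh],[y],t):.4f}, "
          f"{loss_ft([yh],[y],t):.4f}, {c:.4f}")
print("\nzero rows: prediction and truth agree on accept/decline;")
print("the (0.3, 0.9) row shows the strong penalty for crossing the threshold")
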