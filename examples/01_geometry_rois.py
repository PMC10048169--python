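"""Landmark-driven face geometry: alignment angle, face crop, ROI boxes.

Builds one synthetic subject and prints the crop geometry the HARS stage
derives from its 68 landmarks.
"""

from dual_atme import SynthConfig, alignment_angle, make_subject, roi_layout

subject = make_subject(SynthConfig(seed=7), subject_index=0)
lm = subject.landmarks

angle = alignment_angle(lm)
layout = roi_layout(lm, puzzle_size=(56, 56))

print(f"subject            : {subject.subject_id}")
print(f"alignment angle    : {angle:+.3f} deg (0 = eyes already level)")
for name, box in [("face", layout.face), ("left eyebrow", layout.left_eyebrow),
                  ("right eyebrow", layout.right_eyebrow), ("mouth", layout.mouth)]:
    print(f"{name:<14}: left={box.left:6.1f} top={box.top:6.1f} "
          f"right={box.right:6.1f} bottom={box.bottom:6.1f} "
          f"({box.width:.0f}x{box.height:.0f} px)")
print("\nThe face box spans the cheeks (landmarks 1/15) down to the jaw (8),")
print("with brow-to-eye distance d of headroom above the brows; the eyebrow")
print("and mouth boxes are the expanded ROIs tiled into the puzzled image.")
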