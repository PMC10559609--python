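"""Generate a synthetic laryngoscopy dataset and inspect its structure.

Builds 20 patients x 5 frames of white-light / narrow-band frames with
ground-truth lesion masks, labelme polygon annotations and a
patient-disjoint train/verification/test manifest, then validates the
dataset-construction rules.
"""

from pathlib import Path
import tempfile

from laryngoscreen import SynthConfig, generate_dataset, validate_manifest

out = Path(tempfile.mkdtemp(prefix="laryngoscreen_demo_"))
cfg = SynthConfig(seed=42, image_size=(128, 128))
manifest = generate_dataset(cfg, out, n_patients=20, frames_per_patient=5)

by_split = {}
by_label = {}
for rec in manifest:
    by_split[rec.split] = by_split.get(rec.split, 0) + 1
    by_label[rec.label] = by_label.get(rec.label, 0) + 1

print(f"wrote {len(manifest)} frames to {out}")
print("frames per split:", by_split)
print("frames per pathology:", by_label)
print("manifest violations:", validate_manifest(manifest))
# An empty violation list means: patients disjoint across splits, at most
# 10 frames per patient, and every cancer training frame annotated.
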