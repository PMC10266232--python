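"""Full workflow on a constructed scene: image -> weeds -> plans -> report.

A 240x240 frame with two weeds and one crop plant between them.  The
pipeline segments the weeds, orders them, plans one weeding cycle over the
crop cylinder inferred from its bounding box, and verifies the arch never
enters the cylinder.
"""

import json

import numpy as np

from radixweed.pipeline import PipelineConfig, run_pipeline
from radixweed.segmentation import CalibratedCamera, SegConfig

img = np.tile(np.array([130, 85, 60], dtype=np.uint8), (240, 240, 1))  # soil
img[110:130, 20:40] = (60, 180, 50)  # weed 1
img[110:130, 200:220] = (60, 180, 50)  # weed 2
img[95:145, 95:145] = (60, 180, 50)  # crop plant
crop_boxes = [(95, 95, 145, 145)]  # detector output (xmin, ymin, xmax, ymax)

cfg = PipelineConfig(
    seg=SegConfig(mcds=50),
    calib=CalibratedCamera(mm_per_px=1.0, camera_origin_world=(-120.0, -120.0)),
    seed=0,
)
report = run_pipeline(img, crop_boxes, cfg)
print(json.dumps({k: v for k, v in report.items() if k != "weeds_px"}, indent=2))
# one cycle between the two weeds; "collision_free": true means the sampled
# world trajectory stays outside the crop cylinder for its whole length.
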