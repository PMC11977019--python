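import json

import numpy as np
import pytest

from cagewatch.synthetic_scenes import standard_fixture_suite


@pytest.fixture(scope="session")
def suite():
    """Canonical fixture suite at test resolution (320x180, 300 frames)."""
    return standard_fixture_suite((320, 180), 300)


@pytest.fixture()
def via_project(tmp_path):
    """Hand-written VIA 2.x project: 2 frames x 2 regions, one region flagged
    ignore, one polygon region."""
    project = {
        "_via_img_metadata": {
            "frame_000000.png12345": {
                "filename": "frame_000000.png",
                "size": 12345,
                "regions": [
                    {
                        "shape_attributes": {
                            "name": "rect",
                            "x": 10,
                            "y": 20,
                            "width": 30,
                            "height": 40,
                        },
                        "region_attributes": {"id": "macaque_A"},
                    },
                    {
                        "shape_attributes": {
                            "name": "polygon",
                            "all_points_x": [0, 10, 10, 0],
                            "all_points_y": [0, 0, 10, 10],
                        },
                        "region_attributes": {"id": "macaque_B"},
                    },
                ],
            },
            "frame_000001.png999": {
                "filename": "frame_000001.png",
                "size": 999,
                "regions": [
                    {
                        "shape_attributes": {
                            "name": "rect",
                            "x": 5,
                            "y": 5,
                            "width": 10,
                            "height": 10,
                        },
                        "region_attributes": {"id": "macaque_A"},
                    },
                    {
                        "shape_attributes": {
                            "name": "rect",
                            "x": 100,
                            "y": 3,
                            "width": 20,
                            "height": 15,
                        },
                        "region_attributes": {"id": "neighbour", "ignore": "1"},
                    },
                ],
            },
        }
    }
    path = tmp_path / "project.json"
    path.write_text(json.dumps(project))
    return path


@pytest.fixture()
def constant_frames():
    """Factory for streams of constant-valued frames."""
    from cagewatch.io_formats import FrameRef

    def make(values, shape=(40, 60)):
        frames = []
        for i, v in enumerate(values):
            img = np.full(shape + (3,), v, dtype=np.uint8)
            frames.append(FrameRef(video_id="const", frame_index=i, image=img))
        return frames

    return make
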