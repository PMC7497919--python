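import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from vmatgeo.io_formats import Lesion, StructureSet
from vmatgeo.mlc import get_machine


def octa_lesion(lesion_id, center, radius):
    """Lesion whose surface points are the six axis-aligned extreme points:
    bounding box and BEV extents are exact (center ± radius per axis)."""
    center = np.asarray(center, float)
    offsets = radius * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
    )
    return Lesion(id=lesion_id, name=lesion_id, points=center + offsets)


def random_scatter_case(rng, n_lesions, points_per_lesion=24,
                        box_mm=140.0, radius_range=(2.0, 12.0)):
    """n lesions scattered independently in a cranial sphere; small point
    counts keep exhaustive-search oracle comparisons fast."""
    from vmatgeo.synthetic import sphere_surface_points

    lesions = []
    for i in range(n_lesions):
        while True:
            center = rng.uniform(-box_mm / 2, box_mm / 2, size=3)
            radius = rng.uniform(*radius_range)
            if np.linalg.norm(center) + radius <= 85.0:
                break
        pts = sphere_surface_points(center, radius, points_per_lesion,
                                    seed=int(rng.integers(2**31)))
        lesions.append(Lesion(id=f"L{i}", name=f"L{i}", points=pts))
    return StructureSet(lesions=lesions)


def build_rtstruct(path, rois, frame_uid="1.2.3.4.5", modality="RTSTRUCT",
                   slices_per_roi=1):
    """Write a minimal synthetic DICOM RT Structure Set.

    ``rois`` is a list of (name, points) with points an (n,3) array; each
    ROI's points are split into ``slices_per_roi`` contour items.  ``rois``
    may also carry a per-ROI frame UID as (name, points, frame_uid).
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=["vmatgeo-test"])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = "SYN001"

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for i, roi in enumerate(rois, start=1):
        name, points = roi[0], np.asarray(roi[1], float)
        uid = roi[2] if len(roi) > 2 else frame_uid
        item = Dataset()
        item.ROINumber = i
        item.ROIName = name
        item.ReferencedFrameOfReferenceUID = uid
        ds.StructureSetROISequence.append(item)

        rc = Dataset()
        rc.ReferencedROINumber = i
        rc.ContourSequence = []
        for chunk in np.array_split(points, slices_per_roi):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(chunk)
            c.ContourData = [float(v) for v in chunk.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)

    ds.preamble = b"\x00" * 128
    ds.save_as(str(path), enforce_file_format=True)
    return path


@pytest.fixture(scope="session")
def hd120():
    return get_machine("HD120")


@pytest.fixture(scope="session")
def m120():
    return get_machine("M120")


@pytest.fixture
def rng():
    return np.random.default_rng(20160701)


@pytest.fixture
def two_square_polys():
    """Two 10x10 mm squares separated by a 30 mm gap along X: the canonical
    island-blocking fixture (areas 500 mm2 at collimator 0, 200 mm2 at 90)."""
    s1 = np.array([[-25.0, -5.0], [-15.0, -5.0], [-15.0, 5.0], [-25.0, 5.0]])
    s2 = np.array([[15.0, -5.0], [25.0, -5.0], [25.0, 5.0], [15.0, 5.0]])
    return [s1, s2]
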