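"""Programmatic DICOM series fixtures (synthetic, generated at test time)."""

import numpy as np


def write_series(directory, n_slices=4, thickness=2.0, slope=1.0,
                 intercept=0.0, stored_value=100,
                 orientation=(1, 0, 0, 0, 1, 0), rows=8, cols=8):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    series_uid = generate_uid()
    study_uid = generate_uid()
    for i in range(n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = rows, cols
        ds.PixelSpacing = [1.0, 1.0]
        ds.SliceThickness = thickness
        ds.ImageOrientationPatient = list(orientation)
        # z decreases toe-ward; index 0 written most superior
        ds.ImagePositionPatient = [0.0, 0.0, -thickness * i]
        ds.InstanceNumber = i + 1
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.full((rows, cols), stored_value,
                               dtype=np.uint16).tobytes()
        ds.save_as(str(directory / f"slice_{i:03d}.dcm"),
                   enforce_file_format=True)
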