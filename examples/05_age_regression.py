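"""Train the 3D convolutional age regressor on standardized ROI cubes.

Runs the desk-scale protocol on 100 phantoms: ground-truth ROI crops,
standardization to 32-voxel cubes, a 4:1 split and a short cosine-annealed
training run, then prints the error in years on both splits.
"""

from craniage.protocols import age_regression_protocol

result = age_regression_protocol(seed=0, n_volumes=100)
print(f"train: n={result.n_train}, RMSE {result.rmse_train_years:.1f} y")
print(f"test:  n={result.n_test}, RMSE {result.rmse_test_years:.1f} y, "
      f"MAE {result.mae_test_years:.1f} y")
print("The phantom's age cues (joint-gap narrowing, exostoses, bone-brightness")
print("decline) carry an intrinsic noise floor of roughly five years, so a")
print("single-digit test RMSE means the network recovered most of the signal.")
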