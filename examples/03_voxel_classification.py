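"""Classify renal voxels into cortex/medulla/pelvis from their time-courses.

Training uses two synthetic subjects; evaluation is on a third, held-out
subject (leave-one-subject-out discipline).  PCA compresses each
74-point curve into 20 feature aggregates; an RBF-kernel SVM assigns
compartments; unsupervised k-means serves as the literature baseline.
"""

from renodce import fine_seg, metrics
from renodce.phantom import PhantomConfig, make_phantom

cfg = dict(shape=(192, 192, 6), noise_sigma=0.03, pk_dispersion=0.15)
train = {f"s{i}": make_phantom(PhantomConfig(seed=10 + i, **cfg)) for i in range(2)}
test = make_phantom(PhantomConfig(seed=77, **cfg))

sets = [fine_seg.extract_time_courses(ph.series, ph.labels.data > 0, ph.labels, subject=n)
        for n, ph in train.items()]
tcs = fine_seg.concat_time_courses(sets)
pca = fine_seg.fit_pca(tcs, k=20)
print(f"PCA: {pca.k} components explain "
      f"{pca.explained_variance_ratio.sum():.1%} of training variance")

features = fine_seg.transform_pca(pca, tcs)
bx, by = fine_seg.balance_classes(features, tcs.labels, seed=0)
print(f"balanced training set: {len(by)} voxels ({len(by)//3} per class)")
clf = fine_seg.train_classifier(bx, by, training_subjects=sorted(train))

test_tcs = fine_seg.extract_time_courses(test.series, test.labels.data > 0,
                                         test.labels, subject="held_out")
test_feats = fine_seg.transform_pca(pca, test_tcs)
rep = metrics.classification_report(test_tcs.labels, clf.predict(test_feats))
print(f"held-out SVM balanced accuracy: {rep.balanced_accuracy:.3f}")
print(f"  per-class recall: {rep.recall}")

km = fine_seg.kmeans_partition(test_feats, k=3, seed=0, true_labels=test_tcs.labels)
km_rep = metrics.classification_report(test_tcs.labels, km.mapped_labels)
print(f"k-means baseline balanced accuracy: {km_rep.balanced_accuracy:.3f}")
# Balanced accuracy is the mean of per-class true-positive rates, so the
# small pelvis class counts as much as the dominant cortex.
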