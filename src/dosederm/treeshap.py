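"""Path-dependent TreeSHAP for scikit-learn decision trees and forests.

Computes exact Shapley values for a single tree under the path-dependent
feature-perturbation scheme (cover-weighted expectations over unvisited
branches), in O(leaves x depth^2) per sample.  Forest attributions are the
average of per-tree attributions, which for a RandomForestClassifier equals
the attribution of the averaged class-1 probability.

The numba kernels operate on the flattened tree arrays exposed by
``sklearn.tree._tree.Tree``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit
def _extend(feature_indexes, zero_fractions, one_fractions, pweights,
            unique_depth, zero_fraction, one_fraction, feature_index):
    feature_indexes[unique_depth] = feature_index
    zero_fractions[unique_depth] = zero_fraction
    one_fractions[unique_depth] = one_fraction
    pweights[unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pweights[i + 1] += one_fraction * pweights[i] * (i + 1.0) / (unique_depth + 1.0)
        pweights[i] = zero_fraction * pweights[i] * (unique_depth - i) / (unique_depth + 1.0)


@njit
def _unwind(feature_indexes, zero_fractions, one_fractions, pweights,
            unique_depth, path_index):
    one_fraction = one_fractions[path_index]
    zero_fraction = zero_fractions[path_index]
    n = pweights[unique_depth]
    for j in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            t = pweights[j]
            pweights[j] = n * (unique_depth + 1.0) / ((j + 1.0) * one_fraction)
            n = t - pweights[j] * zero_fraction * (unique_depth - j) / (unique_depth + 1.0)
        else:
            pweights[j] = pweights[j] * (unique_depth + 1.0) / (zero_fraction * (unique_depth - j))
    for j in range(path_index, unique_depth):
        feature_indexes[j] = feature_indexes[j + 1]
        zero_fractions[j] = zero_fractions[j + 1]
        one_fractions[j] = one_fractions[j + 1]


@njit
def _unwound_path_sum(zero_fractions, one_fractions, pweights, unique_depth, path_index):
    one_fraction = one_fractions[path_index]
    zero_fraction = zero_fractions[path_index]
    next_one_portion = pweights[unique_depth]
    total = 0.0
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = next_one_portion * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            total += tmp
            next_one_portion = pweights[i] - tmp * zero_fraction * ((unique_depth - i) / (unique_depth + 1.0))
        else:
            total += pweights[i] / (zero_fraction * ((unique_depth - i) / (unique_depth + 1.0)))
    return total


@njit
def _recurse(children_left, children_right, features, thresholds, values,
             node_sample_weight, x, phi, node_index, unique_depth,
             parent_fi, parent_zf, parent_of, parent_pw,
             parent_zero_fraction, parent_one_fraction, parent_feature_index,
             max_path):
    feature_indexes = np.empty(max_path, dtype=np.int64)
    zero_fractions = np.empty(max_path, dtype=np.float64)
    one_fractions = np.empty(max_path, dtype=np.float64)
    pweights = np.empty(max_path, dtype=np.float64)
    for i in range(unique_depth):
        feature_indexes[i] = parent_fi[i]
        zero_fractions[i] = parent_zf[i]
        one_fractions[i] = parent_of[i]
        pweights[i] = parent_pw[i]

    _extend(feature_indexes, zero_fractions, one_fractions, pweights,
            unique_depth, parent_zero_fraction, parent_one_fraction,
            parent_feature_index)

    if children_left[node_index] < 0:  # leaf
        for i in range(1, unique_depth + 1):
            w = _unwound_path_sum(zero_fractions, one_fractions, pweights,
                                  unique_depth, i)
            phi[feature_indexes[i]] += (
                w * (one_fractions[i] - zero_fractions[i]) * values[node_index]
            )
        return

    split_feature = features[node_index]
    if x[split_feature] <= thresholds[node_index]:
        hot = children_left[node_index]
        cold = children_right[node_index]
    else:
        hot = children_right[node_index]
        cold = children_left[node_index]
    w_node = node_sample_weight[node_index]
    hot_zero_fraction = node_sample_weight[hot] / w_node
    cold_zero_fraction = node_sample_weight[cold] / w_node
    incoming_zero_fraction = 1.0
    incoming_one_fraction = 1.0

    path_index = -1
    for i in range(1, unique_depth + 1):
        if feature_indexes[i] == split_feature:
            path_index = i
            break
    if path_index >= 0:
        incoming_zero_fraction = zero_fractions[path_index]
        incoming_one_fraction = one_fractions[path_index]
        _unwind(feature_indexes, zero_fractions, one_fractions, pweights,
                unique_depth, path_index)
        unique_depth -= 1

    _recurse(children_left, children_right, features, thresholds, values,
             node_sample_weight, x, phi, hot, unique_depth + 1,
             feature_indexes, zero_fractions, one_fractions, pweights,
             hot_zero_fraction * incoming_zero_fraction, incoming_one_fraction,
             split_feature, max_path)
    _recurse(children_left, children_right, features, thresholds, values,
             node_sample_weight, x, phi, cold, unique_depth + 1,
             feature_indexes, zero_fractions, one_fractions, pweights,
             cold_zero_fraction * incoming_zero_fraction, 0.0,
             split_feature, max_path)


@njit
def _tree_shap_matrix(children_left, children_right, features, thresholds,
                      values, node_sample_weight, X, phi, max_path):
    fi = np.empty(0, dtype=np.int64)
    zf = np.empty(0, dtype=np.float64)
    of = np.empty(0, dtype=np.float64)
    pw = np.empty(0, dtype=np.float64)
    for r in range(X.shape[0]):
        _recurse(children_left, children_right, features, thresholds, values,
                 node_sample_weight, X[r], phi[r], 0, 0,
                 fi, zf, of, pw, 1.0, 1.0, -1, max_path)


def _tree_arrays(tree):
    """Flatten an sklearn Tree into (structure arrays, class-1 leaf values)."""
    t = tree.tree_
    vals = t.value.reshape(t.node_count, -1)
    if vals.shape[1] > 1:  # classifier: value rows are per-class fractions
        row_sums = vals.sum(axis=1)
        leaf_value = vals[:, 1] / np.where(row_sums > 0, row_sums, 1.0)
    else:
        leaf_value = vals[:, 0]
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        leaf_value.astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        int(t.max_depth),
    )


def tree_shap_values(tree, X: np.ndarray) -> np.ndarray:
    """Shapley values of a fitted sklearn tree for each row of ``X``.

    For classifiers the explained output is the predicted probability of
    class 1; for regressors it is the predicted value.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    cl, cr, feat, thr, val, nsw, depth = _tree_arrays(tree)
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    _tree_shap_matrix(cl, cr, feat, thr, val, nsw, X, phi, depth + 2)
    return phi


def forest_shap_values(forest, X: np.ndarray) -> np.ndarray:
    """Mean per-tree Shapley values of a fitted sklearn forest ensemble."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    for est in forest.estimators_:
        phi += tree_shap_values(est, X)
    phi /= len(forest.estimators_)
    return phi


def expected_value(tree) -> float:
    """Cover-weighted mean prediction of a tree (SHAP base value)."""
    cl, cr, feat, thr, val, nsw, _ = _tree_arrays(tree)
    total = 0.0
    stack = [(0, 1.0)]
    while stack:
        node, w = stack.pop()
        if cl[node] < 0:
            total += w * val[node]
        else:
            stack.append((cl[node], w * nsw[cl[node]] / nsw[node]))
            stack.append((cr[node], w * nsw[cr[node]] / nsw[node]))
    return total
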