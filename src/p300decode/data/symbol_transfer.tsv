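train	test	class	mean	sd
4	4	nontarget	0.841	0.085
5	4	nontarget	0.839	0.083
6	4	nontarget	0.854	0.083
7	4	nontarget	0.858	0.078
8	4	nontarget	0.864	0.077
9	4	nontarget	0.859	0.076
4	4	target	0.779	0.102
5	4	target	0.696	0.119
6	4	target	0.701	0.110
7	4	target	0.686	0.106
8	4	target	0.670	0.110
9	4	target	0.637	0.107
4	4	total	0.812	0.090
5	4	total	0.768	0.096
6	4	total	0.778	0.093
7	4	total	0.772	0.089
8	4	total	0.767	0.089
9	4	total	0.748	0.086
4	5	nontarget	0.796	0.080
5	5	nontarget	0.841	0.079
6	5	nontarget	0.834	0.079
7	5	nontarget	0.840	0.074
8	5	nontarget	0.846	0.081
9	5	nontarget	0.846	0.072
4	5	target	0.737	0.109
5	5	target	0.771	0.102
6	5	target	0.687	0.110
7	5	target	0.689	0.101
8	5	target	0.658	0.112
9	5	target	0.652	0.108
4	5	total	0.767	0.090
5	5	total	0.806	0.090
6	5	total	0.761	0.087
7	5	total	0.765	0.083
8	5	total	0.751	0.087
9	5	total	0.749	0.084
4	6	nontarget	0.792	0.081
5	6	nontarget	0.813	0.080
6	6	nontarget	0.863	0.065
7	6	nontarget	0.840	0.072
8	6	nontarget	0.852	0.072
9	6	nontarget	0.846	0.070
4	6	target	0.762	0.110
5	6	target	0.708	0.140
6	6	target	0.829	0.059
7	6	target	0.737	0.120
8	6	target	0.729	0.119
9	6	target	0.704	0.113
4	6	total	0.779	0.088
5	6	total	0.761	0.099
6	6	total	0.846	0.061
7	6	total	0.789	0.088
8	6	total	0.791	0.086
9	6	total	0.775	0.082
4	7	nontarget	0.782	0.076
5	7	nontarget	0.807	0.073
6	7	nontarget	0.823	0.075
7	7	nontarget	0.855	0.066
8	7	nontarget	0.841	0.069
9	7	nontarget	0.842	0.068
4	7	target	0.740	0.105
5	7	target	0.708	0.109
6	7	target	0.732	0.094
7	7	target	0.816	0.058
8	7	target	0.725	0.087
9	7	target	0.726	0.093
4	7	total	0.761	0.085
5	7	total	0.757	0.085
6	7	total	0.778	0.078
7	7	total	0.835	0.060
8	7	total	0.782	0.074
9	7	total	0.783	0.078
4	8	nontarget	0.776	0.080
5	8	nontarget	0.803	0.074
6	8	nontarget	0.821	0.080
7	8	nontarget	0.827	0.075
8	8	nontarget	0.861	0.067
9	8	nontarget	0.835	0.074
4	8	target	0.753	0.111
5	8	target	0.717	0.122
6	8	target	0.752	0.103
7	8	target	0.753	0.101
8	8	target	0.822	0.066
9	8	target	0.736	0.099
4	8	total	0.764	0.090
5	8	total	0.760	0.091
6	8	total	0.787	0.088
7	8	total	0.790	0.084
8	8	total	0.841	0.065
9	8	total	0.785	0.082
4	9	nontarget	0.770	0.075
5	9	nontarget	0.798	0.074
6	9	nontarget	0.815	0.077
7	9	nontarget	0.827	0.074
8	9	nontarget	0.835	0.070
9	9	nontarget	0.854	0.066
4	9	target	0.727	0.108
5	9	target	0.699	0.111
6	9	target	0.721	0.107
7	9	target	0.740	0.095
8	9	target	0.729	0.096
9	9	target	0.811	0.061
4	9	total	0.748	0.084
5	9	total	0.748	0.084
6	9	total	0.768	0.083
7	9	total	0.783	0.078
8	9	total	0.782	0.077
9	9	total	0.838	0.064
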