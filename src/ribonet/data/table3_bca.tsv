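combination	98.k	116.k	117.k	118.k	119.k	132.k	133.k	134.k	135.k	136.k	88.u	89.u	90.u	113.u	116.u	121.u	127.u
E1_E1	0.52	0.25	-0.14	-0.39	0.38	-0.13	-0.47	-0.57	-0.34	-0.27	1.86	1.57	-0.42	-0.14	-0.69	0.94	-0.53
E1_W1	0.51	0.21	0.42	-0.45	0.55	-0.13	-0.47	-0.58	-0.34	-0.27	1.85	1.56	-0.39	0.07	-0.67	0.95	-0.53
E1_W2	0.53	0.21	0.40	-0.46	0.55	-0.14	-0.48	-0.58	-0.35	-0.28	1.91	1.73	-0.40	0.07	-0.68	0.97	-0.50
E1_W3	0.50	0.18	0.41	-0.45	0.53	-0.20	-0.50	-0.58	-0.34	-0.27	1.93	1.53	-0.39	0.07	-0.66	0.95	-0.53
W1_E1	0.75	0.23	-0.16	-0.4	0.39	-0.14	-0.49	-0.59	-0.35	-0.28	1.88	1.86	-0.43	-0.15	-0.71	0.97	-0.51
W1_W1	0.71	0.19	0.47	-0.45	0.54	-0.13	-0.48	-0.58	-0.34	-0.28	1.89	1.65	-0.39	0.09	-0.67	0.95	-0.53
W1_W2	0.70	0.18	0.41	-0.46	0.54	-0.19	-0.50	-0.58	-0.34	-0.27	1.97	1.64	-0.39	0.07	-0.67	0.96	-0.53
W1_W3	0.71	0.18	0.40	-0.45	0.54	-0.13	-0.48	-0.58	-0.34	-0.27	1.98	1.64	-0.39	0.07	-0.67	0.95	-0.53
W2_E1	0.70	0.22	-0.14	-0.39	0.35	-0.20	-0.50	-0.58	-0.34	-0.27	2.10	1.61	-0.43	-0.18	-0.69	0.97	-0.53
W2_W1	0.71	0.19	0.47	-0.45	0.54	-0.13	-0.48	-0.58	-0.34	-0.28	1.89	1.65	-0.39	0.09	-0.67	0.95	-0.53
W2_W2	0.71	0.18	0.41	-0.45	0.53	-0.13	-0.48	-0.58	-0.34	-0.27	1.96	1.64	-0.39	0.07	-0.67	0.95	-0.53
W2_W3	0.71	0.18	0.40	-0.45	0.54	-0.13	-0.48	-0.58	-0.34	-0.27	1.98	1.64	-0.39	0.07	-0.67	0.95	-0.53
W3_E1	0.44	-0.09	0.44	-0.46	0.69	-0.20	-0.51	-0.59	-0.35	-0.28	1.77	1.68	-0.40	0.09	-0.68	0.97	-0.51
W3_W1	0.52	0.05	-0.11	-0.4	0.50	-0.13	-0.48	-0.58	-0.34	-0.28	1.86	1.58	-0.42	-0.11	-0.69	0.94	-0.53
W3_W2	0.53	-0.01	0.40	-0.47	0.67	-0.14	-0.48	-0.59	-0.35	-0.28	1.86	1.75	-0.40	0.08	-0.69	0.97	-0.51
W3_W3	0.59	-0.05	-0.12	-0.39	0.51	-0.13	-0.47	-0.58	-0.34	-0.27	1.86	1.57	-0.42	-0.12	-0.69	0.94	-0.53
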