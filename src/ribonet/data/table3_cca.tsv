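combination	98.k	116.k	117.k	118.k	119.k	132.k	133.k	134.k	135.k	136.k	88.u	89.u	90.u	113.u	116.u	121.u	127.u
E1_E1	1.49	1.00	0.37	0.58	1.29	-0.60	-0.65	-1.23	-1.13	-1.26	1.22	1.02	0.20	0.67	-0.04	-0.26	-1.57
E1_W1	1.48	0.99	0.45	0.57	1.36	-0.60	-0.66	-1.23	-1.13	-1.27	1.22	1.02	0.27	0.76	0.02	-0.27	-1.58
E1_W2	1.49	0.99	0.45	0.57	1.35	-0.60	-0.66	-1.21	-1.11	-1.24	1.21	1.00	0.27	0.75	0.03	-0.25	-1.57
E1_W3	1.48	0.99	0.45	0.57	1.36	-0.61	-0.67	-1.23	-1.13	-1.27	1.22	0.99	0.27	0.77	0.04	-0.27	-1.59
W1_E1	1.51	0.97	0.35	0.55	1.28	-0.58	-0.64	-1.22	-1.11	-1.25	1.22	1.04	0.18	0.66	-0.05	-0.25	-1.56
W1_W1	1.49	0.99	0.46	0.58	1.35	-0.59	-0.65	-1.22	-1.12	-1.26	1.23	1.03	0.28	0.75	0.03	-0.26	-1.57
W1_W2	1.49	0.99	0.45	0.57	1.36	-0.61	-0.67	-1.23	-1.13	-1.27	1.23	1.01	0.27	0.76	0.03	-0.27	-1.59
W1_W3	1.49	1.00	0.45	0.57	1.36	-0.61	-0.67	-1.22	-1.12	-1.26	1.23	1.00	0.28	0.76	0.03	-0.26	-1.58
W2_E1	1.48	1.00	0.38	0.59	1.32	-0.61	-0.67	-1.22	-1.12	-1.25	1.27	1.01	0.29	0.66	-0.03	-0.25	-1.58
W2_W1	1.49	0.99	0.46	0.58	1.35	-0.59	-0.65	-1.22	-1.12	-1.26	1.23	1.03	0.28	0.75	0.03	-0.26	-1.57
W2_W2	1.49	1.00	0.45	0.57	1.36	-0.61	-0.67	-1.23	-1.12	-1.26	1.23	1.01	0.27	0.76	0.03	-0.26	-1.58
W2_W3	1.49	1.00	0.45	0.57	1.36	-0.61	-0.67	-1.22	-1.12	-1.26	1.23	1.00	0.28	0.76	0.03	-0.26	-1.58
W3_E1	1.46	0.79	0.46	0.58	1.37	-0.59	-0.65	-1.22	-1.12	-1.26	1.14	0.96	0.28	0.77	0.04	-0.26	-1.57
W3_W1	1.48	0.81	0.39	0.59	1.29	-0.59	-0.65	-1.22	-1.12	-1.26	1.22	1.02	0.22	0.69	-0.02	-0.26	-1.57
W3_W2	1.47	0.80	0.45	0.57	1.35	-0.60	-0.65	-1.22	-1.12	-1.25	1.19	1.00	0.27	0.76	0.03	-0.26	-1.57
W3_W3	1.52	0.79	0.38	0.59	1.30	-0.60	-0.66	-1.23	-1.13	-1.26	1.21	1.01	0.21	0.68	-0.03	-0.27	-1.57
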