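taxon	areas
t1	A
t10	A
t11	A
t12	A
t13	A
t14	A
t15	A
t16	A
t17	A
t18	A
t19	A
t2	A
t20	A
t21	A
t22	A
t23	A
t24	AB
t25	B
t26	B
t27	A
t28	A
t29	A
t3	A
t30	B
t31	B
t32	B
t33	BC
t34	A
t35	A
t36	A
t37	A
t38	A
t39	A
t4	A
t40	A
t41	A
t42	AB
t43	A
t44	A
t45	A
t46	A
t47	A
t48	A
t49	A
t5	A
t50	A
t51	A
t52	A
t53	A
t54	A
t55	A
t56	A
t57	A
t6	A
t7	A
t8	A
t9	A
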